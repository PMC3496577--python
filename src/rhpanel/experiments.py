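"""Study-scale validation experiments, reproducible from a single seed.

Each function runs one end-to-end check at the panel's conditions (90
hybrids, ~20% macro- / ~28% microchromosome retention, a breakage rate
giving 200-300 cR maps for a ~7 Mb microchromosome) and returns plain
numbers.  They back both the acceptance test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np

from .calling import build_matrix
from .datasets import N_HYBRIDS, NO_HIT_EST_POSITIVES, no_hit_est_matrix
from .io import ABSENT, PRESENT
from .mapping import (
    ComparativeConfig,
    build_framework,
    comparative_map,
    fit_map,
    linkage_groups,
    order_search,
    robust_map,
)
from .retention import class_retention, marker_retention
from .scaffolds import integrity_report, scan_scaffold
from .simulate import (
    Chromosome,
    QPCRSimConfig,
    SimConfig,
    make_chimeric_scaffolds,
    markers_at,
    simulate_panel,
    simulate_qpcr,
)
from .twopoint import TwoPointCounts, grid_search_fit, two_point_fit

MICRO_RETENTION = 0.281
MACRO_RETENTION = 0.202
BREAKAGE_RATE = 0.35  # breaks/Mb at 6,000 rads (package default calibration)


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# desk-scale checks on the printed no-hit EST counts

def table2_desk_check() -> dict[str, float]:
    """Method means recomputed from the printed positive-hybrid counts.

    Returns the mean positive count per method and the mean retention (in
    percent, positives / 90 hybrids averaged over the 8 markers).
    """
    out: dict[str, float] = {}
    for method in NO_HIT_EST_POSITIVES:
        matrix = no_hit_est_matrix(method)
        fs = [marker_retention(row, mid).f for mid, row in zip(matrix.marker_ids, matrix.calls)]
        n_pos = [int((row == PRESENT).sum()) for row in matrix.calls]
        out[f"mean_positives_{method}"] = float(np.mean(n_pos))
        out[f"mean_retention_pct_{method}"] = float(100.0 * np.mean(fs))
    return out


# ---------------------------------------------------------------------------
# two-point fit vs grid oracle

def twopoint_grid_agreement(n_tables: int = 1000, seed: int = 0) -> dict[str, float]:
    """Numeric ML fit vs dense grid search on random count tables.

    Tables are multinomial draws (N = 90) from the haploid model at uniform
    (theta, r); agreement is the log10-likelihood gap between the numeric
    optimum and a 1000 x 999 grid maximum.
    """
    rng = np.random.default_rng(seed)
    ln10 = np.log(10.0)
    max_gap = 0.0
    n_within = 0
    for _ in range(n_tables):
        theta = rng.uniform(0.0, 1.0)
        r = rng.uniform(0.05, 0.95)
        p11 = (1 - theta) * r + theta * r * r
        p10 = theta * r * (1 - r)
        p00 = 1.0 - p11 - 2 * p10
        n = rng.multinomial(90, [p11, p10, p10, max(p00, 0.0)])
        counts = TwoPointCounts(*map(int, n))
        fit = two_point_fit(counts)
        _, _, ll_grid = grid_search_fit(counts)
        gap = abs(fit.loglik - ll_grid) / ln10
        if fit.loglik < ll_grid - 1e-9:
            gap = max(gap, (ll_grid - fit.loglik) / ln10)
        max_gap = max(max_gap, gap)
        n_within += gap <= 1e-3
    return {
        "n_tables": n_tables,
        "max_log10_gap": max_gap,
        "fraction_within_1e3": n_within / n_tables,
    }


# ---------------------------------------------------------------------------
# panel-scale simulations

def _paper_scale_panel(seed: int, n_markers: int = 7):
    """One microchromosome, n markers at 20-30 cR spacing, 90 hybrids."""
    rng = np.random.default_rng(seed)
    gaps = rng.uniform(0.6, 0.85, size=n_markers - 1)  # 19-26 cR at 0.35/Mb
    positions = 0.5 + np.concatenate(([0.0], np.cumsum(gaps)))
    chrom = Chromosome("c1", float(positions[-1] + 0.5), "micro")
    cfg = SimConfig(
        chromosomes=[chrom],
        breakage_rate=BREAKAGE_RATE,
        retention={"micro": MICRO_RETENTION, "macro": MACRO_RETENTION},
        seed=seed,
    )
    markers = markers_at(chrom, positions)
    truth, matrix = simulate_panel(cfg, markers)
    return cfg, markers, truth, matrix


def _canonical(order):
    t = tuple(order)
    return min(t, t[::-1])


def order_recovery_rate(n_seeds: int = 100, seed: int = 0, n_markers: int = 7) -> float:
    """Fraction of panels whose exhaustive search recovers the true order."""
    hits = 0
    for k in range(n_seeds):
        _, markers, _, matrix = _paper_scale_panel(_sub_seed(seed, k), n_markers)
        true_order = [m.marker_id for m in markers]
        best = order_search(matrix, true_order)
        hits += _canonical(best.marker_ids) == _canonical(true_order)
    return hits / n_seeds


def theta_recovery(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Interval thetas refitted on noiseless panels vs 1 - exp(-rate x gap)."""
    within = total = 0
    worst = 0.0
    for k in range(n_seeds):
        s = _sub_seed(seed, 1000 + k)
        rng = np.random.default_rng(s)
        gaps = rng.uniform(0.6, 0.85, size=6)
        positions = 0.5 + np.concatenate(([0.0], np.cumsum(gaps)))
        chrom = Chromosome("c1", float(positions[-1] + 0.5), "micro")
        cfg = SimConfig(
            chromosomes=[chrom],
            breakage_rate=BREAKAGE_RATE,
            retention={"micro": MICRO_RETENTION, "macro": MACRO_RETENTION},
            fp_rate=0.0,
            fn_rate=0.0,
            unknown_rate=0.0,
            seed=s,
        )
        _, matrix = simulate_panel(cfg, markers_at(chrom, positions))
        fitted = fit_map(matrix)
        expect = 1.0 - np.exp(-BREAKAGE_RATE * gaps)
        # SE from the pair model's Fisher information: every cell derivative
        # w.r.t. theta has magnitude r(1-r), so
        # I(theta) = (r(1-r))^2 (1/P11 + 2/P10 + 1/P00) per hybrid
        r = MICRO_RETENTION
        p11 = (1 - expect) * r + expect * r * r
        p10 = expect * r * (1 - r)
        p00 = 1.0 - p11 - 2 * p10
        info = (r * (1 - r)) ** 2 * (1 / p11 + 2 / p10 + 1 / p00)
        se = 1.0 / np.sqrt(cfg.n_hybrids * info)
        dev = np.abs(fitted.thetas - expect)
        within += int((dev <= 3 * se).sum())
        total += dev.size
        worst = max(worst, float((dev / se).max()))
    return {
        "fraction_within_3se": within / total,
        "worst_deviation_se": worst,
        "n_intervals": total,
    }


def inversion_recovery_rate(n_seeds: int = 100, seed: int = 0) -> float:
    """Comparative mapping vs a reference carrying a reversed 3-marker block.

    The simulated genome's true order differs from the reference by one
    3-marker inversion; recovery means the breakpoint-penalised search
    restores the true order despite the penalty favouring the reference.
    """
    hits = 0
    for k in range(n_seeds):
        _, markers, _, matrix = _paper_scale_panel(_sub_seed(seed, 2000 + k), 6)
        ids = [m.marker_id for m in markers]
        ref = [ids[0], ids[3], ids[2], ids[1], ids[4], ids[5]]
        cc = ComparativeConfig(reference_order=ref, lambda_penalty=3.0)
        cm = comparative_map(matrix, ids, cc)
        hits += _canonical(cm.marker_ids) == _canonical(ids)
    return hits / n_seeds


def chimera_performance(
    n_scaffolds: int = 200, seed: int = 0
) -> dict[str, float]:
    """Sensitivity and false-positive rate of the junction linkage test.

    Half the scaffolds are intact, half chimeric; junction markers sit
    within 100 kb of the join; verdicts at LOD threshold 6 with >= 30
    informative hybrids required to call a junction unsupported.
    """
    n_chim = n_scaffolds // 2
    n_intact = n_scaffolds - n_chim
    cfg = SimConfig(seed=_sub_seed(seed, 3000))
    rng = np.random.default_rng(_sub_seed(seed, 3001))
    markers, _, truth = make_chimeric_scaffolds(
        cfg, n_intact, n_chim, rng, junction_gap_mb=0.1
    )
    _, matrix = simulate_panel(cfg, markers)
    verdicts = [
        scan_scaffold(s, markers, matrix, lod_threshold=6.0, n_min=30)
        for s in sorted(truth)
    ]
    rep = integrity_report(verdicts, truth)
    return {
        "sensitivity": rep["sensitivity"],
        "false_positive_rate": rep["false_positive_rate"],
        "n_scaffolds": n_scaffolds,
    }


def calling_identity(seed: int = 0) -> dict[str, float]:
    """Noiseless qPCR readouts called back into the exact simulated truth."""
    chrom = Chromosome("c1", 7.0, "micro")
    cfg = SimConfig(
        chromosomes=[chrom],
        fp_rate=0.0,
        fn_rate=0.0,
        unknown_rate=0.0,
        seed=_sub_seed(seed, 4000),
    )
    truth, _ = simulate_panel(cfg, markers_per_chrom=12)
    q = QPCRSimConfig(ct_sd=0.0, tm_sd=0.0, neg_no_amp_prob=0.0)
    tab = simulate_qpcr(
        truth.presence, truth.marker_ids, truth.hybrid_ids,
        np.random.default_rng(_sub_seed(seed, 4001)), q,
    )
    called, report = build_matrix(tab)
    expected = np.where(truth.presence, PRESENT, ABSENT)
    mismatches = int((called.calls != expected).sum())
    return {
        "mismatch_calls": mismatches,
        "n_calls": int(expected.size),
        "discarded_markers": report.n_discarded,
    }


# ---------------------------------------------------------------------------
# whole-panel summaries at the study's configuration

def panel_retention_summary(seed: int = 0, n_panels: int = 5) -> dict[str, float]:
    """Class and genome-wide retention of simulated 90-hybrid panels (percent).

    Markers on one chromosome share fragments, so a single panel's class mean
    is noisy; averaging a few independent panels reflects the configured
    rates without changing any panel-level condition.
    """
    from .io import MarkerRecord

    macro, micro, genome = [], [], []
    for k in range(n_panels):
        cfg = SimConfig(seed=_sub_seed(seed, 5000 + k))
        truth, matrix = simulate_panel(cfg, markers_per_chrom=16)
        markers = [
            MarkerRecord(marker_id=m, chrom_class="micro" if m.startswith("chrm") else "macro")
            for m in matrix.marker_ids
        ]
        s = class_retention(matrix, markers)
        macro.append(s.class_means["macro"])
        micro.append(s.class_means["micro"])
        genome.append(s.genome_mean)
    return {
        "macro_retention_pct": 100.0 * float(np.mean(macro)),
        "micro_retention_pct": 100.0 * float(np.mean(micro)),
        "genome_retention_pct": 100.0 * float(np.mean(genome)),
    }


def apl22_scale_map(seed: int = 0) -> dict[str, float]:
    """Map a simulated ~7 Mb microchromosome carrying 24 markers.

    Reports the linkage-group size at LOD 11, the framework size at margin 3,
    the framework map length, and the comparative/robust map statistics —
    the same pipeline stages used for a real microchromosome.
    """
    chrom = Chromosome("c1", 7.0, "micro")
    cfg = SimConfig(
        chromosomes=[chrom],
        breakage_rate=BREAKAGE_RATE,
        retention={"micro": 0.304, "macro": MACRO_RETENTION},
        seed=_sub_seed(seed, 6000),
    )
    markers = markers_at(chrom, np.linspace(0.3, 6.7, 24))
    truth, matrix = simulate_panel(cfg, markers)
    groups = linkage_groups(matrix, 11.0)
    main = groups[0]
    fw = build_framework(matrix, main)
    full = fit_map(matrix)  # all 24 markers in physical order
    out = {
        "largest_group_size_lod11": len(main),
        "framework_size": len(fw.marker_ids),
        "framework_length_cR": fw.length_cr,
        "full_map_length_cR": full.length_cr,
    }
    ids = [m for m in matrix.marker_ids if m in set(main.marker_ids)]
    cc = ComparativeConfig(
        reference_order=list(matrix.marker_ids),
        lambda_penalty=3.0,
        bootstrap_B=50,
        seed=_sub_seed(seed, 6001),
    )
    cm = comparative_map(matrix, ids, cc)
    rm = robust_map(matrix, ids, cc, base_map=cm)
    out["comparative_length_cR"] = cm.length_cr
    out["robust_marker_count"] = sum(1 for s in rm.status.values() if s == "robust")
    return out
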