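"""Synthetic radiation-hybrid panels with full hidden truth.

The generative model is the classical RH process: irradiation breaks each
donor chromosome at Poisson-distributed points (``breakage_rate`` expected
breaks per Mb), each resulting fragment is retained in a hybrid cell line
independently with a class-dependent probability (microchromosomes retain
better than macrochromosomes; retention is boosted near centromeres), and a
marker is truly present in a hybrid iff a retained fragment covers it.
Observed calls add genotyping error (false positive / false negative /
unknown), optional marker-wise WGA dropout, and optionally a qPCR readout
layer (Ct / Tm values per replicate) for the genotype-calling module.

Everything is reproducible from a single seed; per-hybrid randomness uses
spawned substreams so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ABSENT, PRESENT, UNKNOWN, AlignmentSegment, GenotypeMatrix, MarkerRecord


class ParameterError(ValueError):
    """A simulation parameter is outside its valid domain."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_mb: float
    chrom_class: Literal["macro", "micro"]
    centromere_mb: float | None = None

    def __post_init__(self) -> None:
        if self.length_mb <= 0:
            raise ParameterError(f"{self.name}: length_mb must be > 0")
        if self.chrom_class not in ("macro", "micro"):
            raise ParameterError(f"{self.name}: class must be macro or micro")


@dataclass
class SimConfig:
    """Panel-level simulation parameters.

    Defaults emulate the study conditions: a 90-hybrid panel irradiated at
    6,000 rads with ~20% macrochromosome and ~28% microchromosome retention,
    and a breakage rate giving maps of order 200-300 cR for a ~7 Mb
    microchromosome carrying ~24 markers.
    """

    # class retentions are marginal values that already include centromeric
    # enrichment, so the default genome carries no centromeres; set
    # centromere_mb on a chromosome to study the boost explicitly
    chromosomes: list[Chromosome] = field(
        default_factory=lambda: [
            Chromosome("chr1", 60.0, "macro"),
            Chromosome("chr2", 40.0, "macro"),
            Chromosome("chrm1", 7.0, "micro"),
            Chromosome("chrm2", 5.0, "micro"),
        ]
    )
    breakage_rate: float = 0.35  # expected breaks per Mb at 6,000 rads
    retention: dict[str, float] = field(
        default_factory=lambda: {"macro": 0.202, "micro": 0.281}
    )
    centromere_boost: float = 1.5  # multiplicative, clipped so r < 1
    centromere_width_mb: float = 1.0  # rectangular kernel half-support
    n_hybrids: int = 90
    fp_rate: float = 0.005
    fn_rate: float = 0.01
    unknown_rate: float = 0.01
    wga_dropout: dict[str, float] = field(
        default_factory=lambda: {"macro": 0.0, "micro": 0.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.breakage_rate <= 0:
            raise ParameterError("breakage_rate must be > 0")
        if self.n_hybrids <= 0:
            raise ParameterError("n_hybrids must be > 0")
        for name, p in [
            ("fp_rate", self.fp_rate),
            ("fn_rate", self.fn_rate),
            ("unknown_rate", self.unknown_rate),
            *((f"retention[{k}]", v) for k, v in self.retention.items()),
            *((f"wga_dropout[{k}]", v) for k, v in self.wga_dropout.items()),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {p}")
        for k, v in self.retention.items():
            if not 0.0 < v < 1.0:
                raise ParameterError(f"retention[{k}] must be in (0, 1)")
        if self.centromere_boost < 1.0:
            raise ParameterError("centromere_boost must be >= 1")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ParameterError(f"unknown chromosome {name!r}")


@dataclass
class SimTruth:
    """Hidden state of a simulated panel, for recovery tests.

    ``presence[i, j]`` is the true presence of marker i in hybrid j.
    ``breakpoints[j][chrom]`` / ``retained[j][chrom]`` hold each hybrid's
    fragmentation and retained-fragment intervals (Mb, per chromosome).
    """

    marker_ids: list[str]
    hybrid_ids: list[str]
    presence: np.ndarray  # bool, markers x hybrids
    breakpoints: list[dict[str, np.ndarray]]
    retained: list[dict[str, list[tuple[float, float]]]]
    dropped_markers: list[str] = field(default_factory=list)
    scaffold_truth: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fragment / retention primitives

def simulate_fragments(
    length_mb: float, breakage_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-process breakpoints on (0, length_mb), sorted.

    The number of breaks is Poisson(rate x length) and positions are uniform;
    the induced partition of the chromosome is the fragment set.
    """
    if length_mb <= 0 or breakage_rate <= 0:
        raise ParameterError("length_mb and breakage_rate must be > 0")
    n = rng.poisson(breakage_rate * length_mb)
    return np.sort(rng.uniform(0.0, length_mb, size=n))


def fragments_from_breakpoints(
    breakpoints: np.ndarray, length_mb: float
) -> list[tuple[float, float]]:
    """The partition of (0, length) induced by sorted breakpoints."""
    edges = np.concatenate(([0.0], np.asarray(breakpoints, dtype=float), [length_mb]))
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def apply_retention(
    fragments: Sequence[tuple[float, float]],
    config: SimConfig,
    chrom: Chromosome,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Keep each fragment independently with its class retention probability.

    Fragments overlapping the rectangular centromere kernel (width
    ``centromere_width_mb`` centred on ``centromere_mb``) use the boosted
    probability ``min(r * centromere_boost, 1 - 1e-9)``.
    """
    if chrom.chrom_class not in config.retention:
        raise ParameterError(f"no retention configured for class {chrom.chrom_class!r}")
    r = config.retention[chrom.chrom_class]
    kept: list[tuple[float, float]] = []
    half = config.centromere_width_mb / 2.0
    for a, b in fragments:
        p = r
        if chrom.centromere_mb is not None:
            lo, hi = chrom.centromere_mb - half, chrom.centromere_mb + half
            if a <= hi and b >= lo:
                p = min(r * config.centromere_boost, 1.0 - 1e-9)
        if rng.uniform() < p:
            kept.append((a, b))
    return kept


def _covered(retained: Sequence[tuple[float, float]], pos_mb: float) -> bool:
    return any(a <= pos_mb <= b for a, b in retained)


# ---------------------------------------------------------------------------
# marker placement

def default_markers(
    config: SimConfig, markers_per_chrom: int = 24
) -> list[MarkerRecord]:
    """Evenly spaced markers along each chromosome (interior grid)."""
    records = []
    for chrom in config.chromosomes:
        step = chrom.length_mb / (markers_per_chrom + 1)
        for k in range(markers_per_chrom):
            pos_mb = step * (k + 1)
            records.append(
                MarkerRecord(
                    marker_id=f"{chrom.name}_m{k:02d}",
                    expected_chrom=chrom.name,
                    position_bp=int(round(pos_mb * 1e6)) or 1,
                    chrom_class=chrom.chrom_class,
                    source="scaffold",
                )
            )
    return records


def markers_at(
    chrom: Chromosome, positions_mb: Sequence[float], prefix: str | None = None
) -> list[MarkerRecord]:
    """Markers at explicit Mb positions on one chromosome."""
    prefix = prefix or chrom.name
    return [
        MarkerRecord(
            marker_id=f"{prefix}_m{k:02d}",
            expected_chrom=chrom.name,
            position_bp=int(round(p * 1e6)) or 1,
            chrom_class=chrom.chrom_class,
            source="scaffold",
        )
        for k, p in enumerate(positions_mb)
    ]


# ---------------------------------------------------------------------------
# panel simulation

def simulate_panel(
    config: SimConfig,
    markers: Sequence[MarkerRecord] | None = None,
    markers_per_chrom: int = 24,
) -> tuple[SimTruth, GenotypeMatrix]:
    """Simulate a full panel: hidden truth plus observed genotype matrix.

    Observation model per call: a true present flips to absent with
    ``fn_rate``, a true absent flips to present with ``fp_rate``, and any
    call becomes unknown with ``unknown_rate``.  WGA dropout acts marker-wise:
    with the class probability, a marker's region fails amplification and the
    marker reads absent in every hybrid.
    """
    if markers is None:
        markers = default_markers(config, markers_per_chrom)
    marker_ids = [m.marker_id for m in markers]
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for i, m in enumerate(markers):
        if m.expected_chrom is None or m.position_bp is None:
            raise ParameterError(f"marker {m.marker_id} lacks a simulated position")
        by_chrom.setdefault(m.expected_chrom, []).append((i, m.position_bp / 1e6))

    ss = np.random.SeedSequence(config.seed)
    hybrid_seeds, marker_seed = ss.spawn(2)
    marker_rng = np.random.Generator(np.random.PCG64(marker_seed))
    hybrid_streams = hybrid_seeds.spawn(config.n_hybrids)

    n_m, n_h = len(markers), config.n_hybrids
    presence = np.zeros((n_m, n_h), dtype=bool)
    calls = np.zeros((n_m, n_h), dtype=np.int8)
    breakpoints: list[dict[str, np.ndarray]] = []
    retained_all: list[dict[str, list[tuple[float, float]]]] = []

    for j in range(n_h):
        rng = np.random.Generator(np.random.PCG64(hybrid_streams[j]))
        bp_j: dict[str, np.ndarray] = {}
        ret_j: dict[str, list[tuple[float, float]]] = {}
        for chrom_name, placed in by_chrom.items():
            chrom = config.chromosome(chrom_name)
            bps = simulate_fragments(chrom.length_mb, config.breakage_rate, rng)
            frags = fragments_from_breakpoints(bps, chrom.length_mb)
            kept = apply_retention(frags, config, chrom, rng)
            bp_j[chrom_name] = bps
            ret_j[chrom_name] = kept
            for i, pos_mb in placed:
                presence[i, j] = _covered(kept, pos_mb)
        breakpoints.append(bp_j)
        retained_all.append(ret_j)
        # observation noise, drawn from the same per-hybrid stream
        u_flip = rng.uniform(size=n_m)
        u_unk = rng.uniform(size=n_m)
        for i in range(n_m):
            true = presence[i, j]
            obs = PRESENT if true else ABSENT
            if true and u_flip[i] < config.fn_rate:
                obs = ABSENT
            elif not true and u_flip[i] < config.fp_rate:
                obs = PRESENT
            if u_unk[i] < config.unknown_rate:
                obs = UNKNOWN
            calls[i, j] = obs

    dropped: list[str] = []
    for i, m in enumerate(markers):
        p_drop = config.wga_dropout.get(m.chrom_class, 0.0)
        if p_drop > 0 and marker_rng.uniform() < p_drop:
            calls[i, :] = ABSENT
            dropped.append(m.marker_id)

    hybrid_ids = [f"H{j:03d}" for j in range(n_h)]
    truth = SimTruth(
        marker_ids=marker_ids,
        hybrid_ids=hybrid_ids,
        presence=presence,
        breakpoints=breakpoints,
        retained=retained_all,
        dropped_markers=dropped,
    )
    matrix = GenotypeMatrix(marker_ids=marker_ids, hybrid_ids=hybrid_ids, calls=calls)
    return truth, matrix


# ---------------------------------------------------------------------------
# qPCR readout layer

POS_CONTROL = "DUCK_POS"
NEG_CONTROL = "HAMSTER_NEG"


@dataclass
class QPCRSimConfig:
    """Readout-level parameters for the qPCR layer.

    Positives amplify early at the marker-specific melting temperature;
    negatives amplify late (cross-amplification of the recipient background)
    with an off-target Tm, or not at all.  The duck positive control sits near
    ``ct_pos_mean`` (12 cycles under pre-amplification) and the hamster
    negative control late.  The WGA condition shifts positives later
    (``wga_ct_shift``; the study observed ~22-cycle positive controls) and
    loses some amplifications outright.
    """

    ct_pos_mean: float = 12.0
    ct_sd: float = 1.0
    ct_neg_control_mean: float = 25.0
    ct_neg_hybrid_mean: float = 26.0
    tm_specific: float = 85.0
    tm_sd: float = 0.15
    tm_offtarget_shift: float = 4.0
    neg_no_amp_prob: float = 0.5
    n_replicates: int = 2
    wga_ct_shift: float = 10.0
    wga_pos_no_amp_prob: float = 0.3


def simulate_qpcr(
    presence: np.ndarray,
    marker_ids: Sequence[str],
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    config: QPCRSimConfig | None = None,
    condition: Literal["preamp", "wga"] = "preamp",
) -> pd.DataFrame:
    """Simulate per-replicate Ct/Tm readouts from a true presence matrix.

    Returns a long table with columns ``marker_id, sample_id, replicate, ct,
    tm``; ``ct`` is NaN for no amplification.  Control rows use the
    ``DUCK_POS`` / ``HAMSTER_NEG`` sample ids.
    """
    cfg = config or QPCRSimConfig()
    ct_shift = cfg.wga_ct_shift if condition == "wga" else 0.0
    pos_no_amp = cfg.wga_pos_no_amp_prob if condition == "wga" else 0.0
    rows: list[tuple] = []

    def emit(marker: str, sample: str, rep: int, positive: bool) -> None:
        if positive:
            if pos_no_amp > 0 and rng.uniform() < pos_no_amp:
                rows.append((marker, sample, rep, np.nan, np.nan))
                return
            ct = cfg.ct_pos_mean + ct_shift + rng.normal(0.0, cfg.ct_sd)
            tm = cfg.tm_specific + rng.normal(0.0, cfg.tm_sd)
        else:
            if rng.uniform() < cfg.neg_no_amp_prob:
                rows.append((marker, sample, rep, np.nan, np.nan))
                return
            ct = cfg.ct_neg_hybrid_mean + rng.normal(0.0, cfg.ct_sd)
            tm = cfg.tm_specific + cfg.tm_offtarget_shift + rng.normal(0.0, cfg.tm_sd)
        rows.append((marker, sample, rep, float(ct), float(tm)))

    presence = np.asarray(presence, dtype=bool)
    for i, marker in enumerate(marker_ids):
        for rep in range(1, cfg.n_replicates + 1):
            ct_pc = cfg.ct_pos_mean + ct_shift + rng.normal(0.0, cfg.ct_sd)
            tm_pc = cfg.tm_specific + rng.normal(0.0, cfg.tm_sd)
            rows.append((marker, POS_CONTROL, rep, float(ct_pc), float(tm_pc)))
            ct_nc = cfg.ct_neg_control_mean + rng.normal(0.0, cfg.ct_sd)
            tm_nc = cfg.tm_specific + cfg.tm_offtarget_shift + rng.normal(0.0, cfg.tm_sd)
            rows.append((marker, NEG_CONTROL, rep, float(ct_nc), float(tm_nc)))
            for j, sample in enumerate(sample_ids):
                emit(marker, sample, rep, bool(presence[i, j]))

    return pd.DataFrame(
        rows, columns=["marker_id", "sample_id", "replicate", "ct", "tm"]
    )


# ---------------------------------------------------------------------------
# chimeric scaffolds

def make_chimeric_scaffolds(
    config: SimConfig,
    n_intact: int,
    n_chimeric: int,
    rng: np.random.Generator,
    scaffold_len_mb: float = 2.0,
    junction_gap_mb: float = 0.1,
) -> tuple[list[MarkerRecord], list[AlignmentSegment], dict[str, dict]]:
    """Build intact and chimeric scaffolds with junction-flanking marker pairs.

    Intact scaffolds are contiguous intervals of one chromosome; chimeric
    scaffolds concatenate half-intervals from two different chromosomes, with
    the junction in the middle.  Each scaffold gets a marker pair at most
    ``junction_gap_mb`` apart in scaffold coordinates, straddling the
    junction point (for intact scaffolds, the scaffold midpoint).  Returns
    markers, Narcisse-style alignment segments and per-scaffold truth labels.
    """
    if n_chimeric > 0 and len(config.chromosomes) < 2:
        raise ParameterError("chimeric scaffolds need at least 2 chromosomes")
    markers: list[MarkerRecord] = []
    segments: list[AlignmentSegment] = []
    truth: dict[str, dict] = {}
    half = scaffold_len_mb / 2.0
    gap = junction_gap_mb / 2.0

    def random_interval(chrom: Chromosome) -> float:
        lo = half + gap
        hi = chrom.length_mb - half - gap
        if hi <= lo:
            raise ParameterError(
                f"chromosome {chrom.name} too short for {scaffold_len_mb} Mb scaffolds"
            )
        return float(rng.uniform(lo, hi))

    def mk(marker_id, chrom, pos_mb, sca, offset_mb):
        return MarkerRecord(
            marker_id=marker_id,
            expected_chrom=chrom.name,
            position_bp=max(1, int(round(pos_mb * 1e6))),
            scaffold_id=sca,
            scaffold_offset_bp=max(1, int(round(offset_mb * 1e6))),
            chrom_class=chrom.chrom_class,
            source="scaffold",
        )

    for k in range(n_intact):
        sca = f"sim_sca{k:03d}"
        chrom = config.chromosomes[int(rng.integers(len(config.chromosomes)))]
        centre = random_interval(chrom)
        start = centre - half
        segments.append(
            AlignmentSegment(
                scaffold_id=sca,
                scaffold_start_bp=1,
                scaffold_end_bp=int(scaffold_len_mb * 1e6),
                ref_chrom=chrom.name,
                ref_start_bp=max(1, int(round(start * 1e6))),
                ref_end_bp=int(round((start + scaffold_len_mb) * 1e6)),
                orientation="+",
            )
        )
        markers.append(mk(f"{sca}A", chrom, centre - gap, sca, half - gap))
        markers.append(mk(f"{sca}B", chrom, centre + gap, sca, half + gap))
        truth[sca] = {"status": "intact", "chromosomes": [chrom.name]}

    for k in range(n_chimeric):
        sca = f"sim_sca{n_intact + k:03d}"
        ia, ib = rng.choice(len(config.chromosomes), size=2, replace=False)
        ca, cb = config.chromosomes[int(ia)], config.chromosomes[int(ib)]
        centre_a, centre_b = random_interval(ca), random_interval(cb)
        # left half of the scaffold comes from ca, right half from cb
        segments.append(
            AlignmentSegment(
                scaffold_id=sca,
                scaffold_start_bp=1,
                scaffold_end_bp=int(half * 1e6),
                ref_chrom=ca.name,
                ref_start_bp=max(1, int(round((centre_a - half) * 1e6))),
                ref_end_bp=int(round(centre_a * 1e6)),
                orientation="+",
            )
        )
        segments.append(
            AlignmentSegment(
                scaffold_id=sca,
                scaffold_start_bp=int(half * 1e6) + 1,
                scaffold_end_bp=int(scaffold_len_mb * 1e6),
                ref_chrom=cb.name,
                ref_start_bp=max(1, int(round(centre_b * 1e6))),
                ref_end_bp=int(round((centre_b + half) * 1e6)),
                orientation="+",
            )
        )
        markers.append(mk(f"{sca}A", ca, centre_a - gap, sca, half - gap))
        markers.append(mk(f"{sca}B", cb, centre_b + gap, sca, half + gap))
        truth[sca] = {"status": "chimeric", "chromosomes": [ca.name, cb.name]}

    return markers, segments, truth
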