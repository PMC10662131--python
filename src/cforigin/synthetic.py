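"""Synthetic data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its configuration and seed: reference
atlases with planted cell-type-specific marker regions, targeted amplicon
reads drawn from known cell-type mixtures with bisulfite conversion failure
and sequencing error, clinical-style cohorts with group-specific GE/ml
levels, block-level bulk mixtures for deconvolution, and platelet-style WGBS
chromosome counts with mitochondrial enrichment and chromosomal skew.

Cohort group means default to the clinically observed regimes for
megakaryocyte cfDNA (healthy 510, Essential Thrombocythemia 4242, Immune
Thrombocytopenia 1608, hypoplastic marrow 250 GE/ml) and erythroblast cfDNA
(healthy 7 vs thalassemia 1658 GE/ml); see docs/methods.md for the choices
the generators make where no observed value exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import CellTypeMethylome, CpGSite, MarkerRegion
from .platelet import ChromCounts
from .targeted import GE_PER_NG, ReadPattern

DEFAULT_CELL_TYPES = ("MK", "erythroblast", "granulocyte", "monocyte", "T_cell")

#: Human-like chromosome lengths (bp) used by the WGBS count generator.
HUMAN_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566, "chrX": 155_270_560, "chrY": 59_373_566,
    "chrM": 16_571,
}


# ---------------------------------------------------------------------------
# reference atlas with planted markers


@dataclass(frozen=True)
class PlantedMarkerSpec:
    """How many marker regions to plant for one cell type, and their shape."""

    cell_type: str
    count: int
    direction: str = "hypo"
    cpgs_per_region: int = 5


@dataclass(frozen=True)
class AtlasConfig:
    """Synthetic reference-atlas regime.

    Background CpGs sit near ``background_beta`` (0.85, a methylated
    genome-wide baseline); planted regions are driven to ``planted_low``
    (0.03) in the target and ``planted_high`` (0.97) elsewhere, comfortably
    inside the <0.05 / >0.95 planting regime. ``beta_noise`` is a
    beta-distribution concentration for per-sample, per-site variation
    (None = noise-free means); observed betas are binomial draws at ``depth``
    around the per-sample level (a beta-binomial observation model).
    """

    n_cell_types: int = 5
    n_cpgs: int = 2_000
    samples_per_type: int = 2
    depth: int = 30
    cpg_spacing_bp: int = 25
    background_beta: float = 0.85
    planted_low: float = 0.03
    planted_high: float = 0.97
    beta_noise: float | None = None
    buffer_cpgs: int = 6  # non-specific CpGs kept between planted regions
    planted: tuple[PlantedMarkerSpec, ...] = (
        PlantedMarkerSpec("MK", 8),
        PlantedMarkerSpec("erythroblast", 20),
    )
    cell_types: tuple[str, ...] = ()

    def resolved_cell_types(self) -> tuple[str, ...]:
        if self.cell_types:
            return self.cell_types
        base = DEFAULT_CELL_TYPES
        if self.n_cell_types <= len(base):
            return base[: self.n_cell_types]
        return base + tuple(f"cell_type_{i}" for i in range(len(base), self.n_cell_types))


def simulate_atlas(
    config: AtlasConfig = AtlasConfig(), seed: int | None = None
) -> tuple[list[CellTypeMethylome], list[MarkerRegion]]:
    """Generate per-sample reference methylomes plus the planted truth regions.

    Returns one methylome per (cell type, sample) and the list of planted
    marker regions for recall/precision scoring of the discovery pipeline.
    """
    rng = np.random.default_rng(seed)
    cell_types = config.resolved_cell_types()
    for spec in config.planted:
        if spec.cell_type not in cell_types:
            raise ValueError(f"planted cell type {spec.cell_type!r} not in atlas")

    if config.planted:
        slot_size = max(s.cpgs_per_region for s in config.planted) + config.buffer_cpgs
        n_slots = config.n_cpgs // slot_size
        n_needed = sum(s.count for s in config.planted)
        if n_needed > n_slots:
            raise ValueError(
                f"planted regions exceed capacity: need {n_needed} slots, have {n_slots}"
            )
        slot_order = rng.permutation(n_slots)[:n_needed]
    else:
        slot_size, slot_order = 0, np.empty(0, dtype=int)

    positions = np.arange(config.n_cpgs, dtype=np.int64) * config.cpg_spacing_bp
    chrom = "chr1"
    means = np.full((config.n_cpgs, len(cell_types)), config.background_beta)

    truth: list[MarkerRegion] = []
    si = 0
    for spec in config.planted:
        ci = cell_types.index(spec.cell_type)
        lo_val, hi_val = config.planted_low, config.planted_high
        if spec.direction == "hyper":
            lo_val, hi_val = hi_val, lo_val
        for _ in range(spec.count):
            start_idx = int(slot_order[si]) * slot_size
            si += 1
            idx = slice(start_idx, start_idx + spec.cpgs_per_region)
            means[idx, :] = hi_val
            means[idx, ci] = lo_val
            sites = tuple(CpGSite(chrom, int(p)) for p in positions[idx])
            truth.append(
                MarkerRegion(
                    chromosome=chrom,
                    start=sites[0].position,
                    end=sites[-1].position + 2,
                    target_cell_type=spec.cell_type,
                    direction=spec.direction,
                    cpg_sites=sites,
                )
            )
    truth.sort(key=lambda r: (r.chromosome, r.start))

    methylomes: list[CellTypeMethylome] = []
    depth = np.full(config.n_cpgs, config.depth, dtype=np.int64)
    for ci, ct in enumerate(cell_types):
        for s in range(config.samples_per_type):
            mu = means[:, ci]
            if config.beta_noise is None:
                beta = mu.copy()
            else:
                conc = config.beta_noise
                p = rng.beta(np.clip(mu, 1e-6, None) * conc,
                             np.clip(1 - mu, 1e-6, None) * conc)
                k = rng.binomial(config.depth, p)
                beta = k / config.depth
            methylomes.append(
                CellTypeMethylome.from_arrays(
                    ct, f"{ct}_s{s}", np.repeat(chrom, config.n_cpgs), positions, beta, depth
                )
            )
    return methylomes, truth


# ---------------------------------------------------------------------------
# targeted amplicon reads


def simulate_amplicon_reads(
    marker_id: str,
    true_fraction: float,
    n_reads: int,
    n_cpgs: int = 5,
    conversion_failure_rate: float = 0.005,
    sequencing_error_rate: float = 0.001,
    non_cpg_c_per_read: int = 8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPattern], int]:
    """Draw amplicon molecules from a two-population mixture.

    Each molecule originates from the marker's target cell type (fully
    unmethylated) with probability ``true_fraction``, else from background
    (fully methylated). Bisulfite conversion failure then flips U->M per CpG
    independently; sequencing error flips calls symmetrically. Non-CpG
    cytosine counts are drawn consistently with the conversion failure rate.
    Returns (reads, number of unmethylated-origin molecules).
    """
    for name, r in (("true_fraction", true_fraction),
                    ("conversion_failure_rate", conversion_failure_rate),
                    ("sequencing_error_rate", sequencing_error_rate)):
        if not (0 <= r <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    unmeth_origin = rng.random(n_reads) < true_fraction
    meth = np.broadcast_to(~unmeth_origin[:, None], (n_reads, n_cpgs)).copy()
    # conversion failure: a truly unmethylated C escapes conversion, reads CG
    if conversion_failure_rate > 0:
        fail = rng.random((n_reads, n_cpgs)) < conversion_failure_rate
        meth |= ~meth & fail
    if sequencing_error_rate > 0:
        err = rng.random((n_reads, n_cpgs)) < sequencing_error_rate
        meth ^= err
    chars = np.where(meth, np.uint8(ord("M")), np.uint8(ord("U")))
    unconverted = rng.binomial(non_cpg_c_per_read, conversion_failure_rate, size=n_reads)
    reads = [
        ReadPattern(
            marker_id=marker_id,
            calls=chars[i].tobytes().decode("ascii"),
            non_cpg_c_total=non_cpg_c_per_read,
            non_cpg_c_unconverted=int(unconverted[i]),
        )
        for i in range(n_reads)
    ]
    return reads, int(unmeth_origin.sum())


# ---------------------------------------------------------------------------
# clinical-style cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One clinical group: size, mean target-cell GE/ml, and cfDNA level.

    GE/ml varies between individuals log-normally with sigma ``dispersion``
    (arithmetic mean preserved); total cfDNA ng/ml likewise with sigma
    ``cfdna_sigma``.
    """

    name: str
    n_samples: int
    mean_ge_per_ml: float
    cfdna_ng_per_ml: float
    dispersion: float = 0.25
    cfdna_sigma: float = 0.20


@dataclass(frozen=True)
class CohortConfig:
    """Targeted-assay cohort regime: groups, marker panel and read model."""

    groups: tuple[GroupSpec, ...]
    cell_type: str = "MK"
    n_markers: int = 4
    cpgs_per_marker: int = 5
    reads_per_marker: int = 2_000
    max_methylated: int = 1
    conversion_failure_rate: float = 0.005
    sequencing_error_rate: float = 0.001
    non_cpg_c_per_read: int = 8

    def __post_init__(self) -> None:
        for g in self.groups:
            mean_fraction = g.mean_ge_per_ml / (g.cfdna_ng_per_ml * GE_PER_NG)
            if mean_fraction > 1:
                raise ValueError(
                    "inconsistent cohort parameters: group "
                    f"{g.name!r} implies unmethylated fraction {mean_fraction:.2f} > 1"
                )

    def panel(self) -> dict[str, tuple[str, int]]:
        return {
            f"{self.cell_type}_marker_{i}": (self.cell_type, self.max_methylated)
            for i in range(self.n_markers)
        }


def default_mk_cohort(
    n_healthy: int = 77, n_itp: int = 5, n_et: int = 5, n_hypoplastic: int = 5
) -> CohortConfig:
    """Megakaryocyte-cfDNA cohort at the observed group means (GE/ml)."""
    return CohortConfig(
        groups=(
            GroupSpec("healthy", n_healthy, 510.0, 10.0),
            GroupSpec("ITP", n_itp, 1608.0, 20.0),
            GroupSpec("ET", n_et, 4242.0, 35.0),
            GroupSpec("hypoplastic_BM", n_hypoplastic, 250.0, 10.0),
        ),
        cell_type="MK",
        max_methylated=1,
    )


def default_erythroblast_cohort(n_healthy: int = 77, n_thal: int = 3) -> CohortConfig:
    """Erythroblast-cfDNA cohort: healthy vs thalassemia major."""
    return CohortConfig(
        groups=(
            GroupSpec("healthy", n_healthy, 7.0, 10.0),
            GroupSpec("thalassemia", n_thal, 1658.0, 20.0),
        ),
        cell_type="erythroblast",
        max_methylated=0,
    )


@dataclass
class CohortSim:
    """A simulated cohort: reads, per-sample metadata and the marker panel."""

    metadata: pd.DataFrame
    reads: dict[str, dict[str, list[ReadPattern]]]  # sample -> marker -> reads
    panel: dict[str, tuple[str, int]]
    config: CohortConfig


def simulate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> CohortSim:
    """Simulate a full targeted-assay cohort with known per-sample truth.

    Per sample, the true GE/ml is a log-normal draw about its group mean; the
    implied unmethylated fraction (GE/ml divided by ng/ml x 303) drives the
    amplicon read simulator for every marker of the panel. Draws implying a
    fraction > 0.98 are redrawn so the molecule mixture stays physical.
    """
    if config is None:
        config = default_mk_cohort()
    rng = np.random.default_rng(seed)
    panel = config.panel()

    meta_rows = []
    reads: dict[str, dict[str, list[ReadPattern]]] = {}
    for g in config.groups:
        for i in range(g.n_samples):
            sample_id = f"{g.name}_{i:03d}"
            for _ in range(100):
                s = g.dispersion
                ge = g.mean_ge_per_ml * np.exp(rng.normal(-0.5 * s * s, s))
                sc = g.cfdna_sigma
                ng = g.cfdna_ng_per_ml * np.exp(rng.normal(-0.5 * sc * sc, sc))
                fraction = ge / (ng * GE_PER_NG)
                if fraction <= 0.98:
                    break
            else:
                raise ValueError("inconsistent cohort parameters: fraction stuck > 1")
            sample_reads: dict[str, list[ReadPattern]] = {}
            for marker_id in panel:
                r, _ = simulate_amplicon_reads(
                    marker_id,
                    true_fraction=fraction,
                    n_reads=config.reads_per_marker,
                    n_cpgs=config.cpgs_per_marker,
                    conversion_failure_rate=config.conversion_failure_rate,
                    sequencing_error_rate=config.sequencing_error_rate,
                    non_cpg_c_per_read=config.non_cpg_c_per_read,
                    rng=rng,
                )
                sample_reads[marker_id] = r
            reads[sample_id] = sample_reads
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "group": g.name,
                    "cfdna_ng_per_ml": float(ng),
                    "true_ge_per_ml": float(ge),
                    "true_fraction": float(fraction),
                }
            )
    return CohortSim(
        metadata=pd.DataFrame(meta_rows), reads=reads, panel=panel, config=config
    )


# ---------------------------------------------------------------------------
# block-level bulk mixtures (deconvolution inputs)


def simulate_mixture(
    atlas_matrix: np.ndarray,
    proportions: np.ndarray,
    depth: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bulk block-level betas for a known mixture of reference cell types.

    Noise-free when ``depth`` is None (b = A x exactly); otherwise each block
    beta is a binomial draw at the given read depth (b_i ~ Bin(depth, (Ax)_i)
    / depth), the sampling noise of a methylation estimate at that coverage.
    """
    x = np.asarray(proportions, dtype=float)
    if np.any(x < 0) or not np.isclose(x.sum(), 1.0):
        raise ValueError("proportions must be nonnegative and sum to 1")
    b = atlas_matrix @ x
    if depth is None:
        return b
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.binomial(depth, np.clip(b, 0, 1)) / depth


# ---------------------------------------------------------------------------
# platelet-style WGBS chromosome counts


@dataclass(frozen=True)
class WgbsConfig:
    """Platelet-WGBS count regime: mitochondrial enrichment plus nuclear skew.

    Nuclear chromosomes share 1 - ``mt_fraction`` of reads proportionally to
    reference length, modulated by per-chromosome ``skew`` multipliers
    (defaults mimic the observed chr4 over- / chr17 under-representation).
    """

    n_reads: int = 100_000
    mt_fraction: float = 0.59
    skew: tuple[tuple[str, float], ...] = (("chr4", 1.3), ("chr17", 0.7))
    lengths: tuple[tuple[str, int], ...] = tuple(HUMAN_CHROM_LENGTHS.items())
    include_y: bool = False


def simulate_wgbs_counts(
    config: WgbsConfig = WgbsConfig(), seed: int | None = None
) -> tuple[ChromCounts, dict[str, float]]:
    """Multinomial chromosome read counts with MT enrichment and skew.

    Returns (counts, expected fractions) — the expectation is the ground
    truth for representation estimates.
    """
    lengths = dict(config.lengths)
    if not config.include_y:
        lengths.pop("chrY", None)
    mt_name = next(n for n in ("chrM", "MT", "chrMT", "M") if n in lengths)
    skew = dict(config.skew)
    nuclear = {c: l for c, l in lengths.items() if c != mt_name}
    w = np.array([nuclear[c] * skew.get(c, 1.0) for c in nuclear], dtype=float)
    w = w / w.sum() * (1.0 - config.mt_fraction)
    names = list(nuclear) + [mt_name]
    probs = np.append(w, config.mt_fraction)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("expected chromosome fractions must sum to 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(config.n_reads, probs)
    counts = ChromCounts(
        counts={c: int(k) for c, k in zip(names, draws)},
        lengths={c: lengths[c] for c in names},
    )
    return counts, dict(zip(names, map(float, probs)))


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator regimes plus the mandatory seed (CLI surface)."""

    seed: int
    atlas: AtlasConfig = AtlasConfig()
    cohort: CohortConfig = field(default_factory=default_mk_cohort)
    wgbs: WgbsConfig = WgbsConfig()

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)
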