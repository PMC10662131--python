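"""Targeted bisulfite amplicon analysis: per-molecule methylation patterns,
bisulfite-conversion QC, and cell-type-specific cfDNA concentration in
haploid genome equivalents per ml plasma (GE/ml).

Each sequenced molecule carries one call per CpG of its marker amplicon:
'M' (read as CG, methylated), 'U' (read as TG, unmethylated) or 'N' (no
call). A molecule counts as *unmethylated* — i.e. derived from the marker's
target cell type — when all of its CpGs are unmethylated, allowing up to
``max_methylated`` exceptions (0 for erythroblast-type markers, 1 for
megakaryocyte-type markers). The fraction of unmethylated molecules among
all sequenced molecules of a marker, multiplied by the sample's total cfDNA
concentration (ng/ml) and by 303 (1000 / 3.3 pg per haploid genome, printed
as the rounded factor 303), yields the target cell type's GE/ml.

Bisulfite conversion efficiency is audited at non-CpG cytosines, which are
unmethylated in human DNA and must read as T after full conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: ng/ml -> GE/ml conversion factor as printed (haploid genome mass 3.3 pg).
GE_PER_NG = 303.0
#: Unrounded alternative, 1000 / 3.3.
GE_PER_NG_EXACT = 1000.0 / 3.3


class MoleculeClass(Enum):
    UNMETHYLATED = "unmethylated_molecule"
    OTHER = "other"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class ReadPattern:
    """One sequenced molecule: per-CpG calls plus non-CpG conversion evidence."""

    marker_id: str
    calls: str  # string over {M, U, N}, one char per amplicon CpG
    non_cpg_c_total: int = 0
    non_cpg_c_unconverted: int = 0

    def __post_init__(self) -> None:
        if set(self.calls) - set("MUN"):
            raise ValueError(f"calls must be over MUN, got {self.calls!r}")
        if not (0 <= self.non_cpg_c_unconverted <= self.non_cpg_c_total):
            raise ValueError("need 0 <= unconverted <= total non-CpG cytosines")


@dataclass(frozen=True)
class ClassificationRule:
    """Molecule-calling rule: tolerated methylated-CpG count and coverage policy.

    ``max_methylated`` is a fixed per-marker-panel property (0 for
    erythroblast markers, 1 for megakaryocyte markers), not inferred from
    data. With ``require_full_coverage`` (default), molecules with any
    no-call CpG are excluded from both numerator and denominator.
    """

    max_methylated: int = 0
    require_full_coverage: bool = True

    def __post_init__(self) -> None:
        if self.max_methylated < 0:
            raise ValueError("max_methylated must be >= 0")


@dataclass
class MarkerFraction:
    """Unmethylated-molecule fraction for one marker in one sample."""

    marker_id: str
    fraction: float | None  # None when no non-excluded reads
    n_reads: int  # non-excluded molecules (the denominator)
    n_unmethylated: int
    low_confidence: bool


@dataclass
class ConversionQC:
    """Sample-level bisulfite conversion rate from pooled non-CpG cytosines."""

    sample_id: str
    conversion_rate: float
    passed: bool


@dataclass
class SampleQuant:
    """Per-sample quantification: marker fractions, cell-type aggregates, GE/ml."""

    sample_id: str
    cfdna_ng_per_ml: float
    marker_fractions: dict[str, MarkerFraction]
    cell_type_fractions: dict[str, float | None]
    ge_per_ml: dict[str, float | None]
    aggregation_method: str
    qc: ConversionQC | None = None
    extra: dict = field(default_factory=dict)


def classify_read(read: ReadPattern, rule: ClassificationRule) -> MoleculeClass:
    """Classify one molecule as unmethylated, other, or excluded.

    Excluded when any CpG is uncalled and full coverage is required; otherwise
    unmethylated iff the number of methylated CpGs is within the rule's
    tolerance and at least one CpG actually read unmethylated.
    """
    if not read.calls:
        raise ValueError("read has no CpG calls")
    if rule.max_methylated >= len(read.calls):
        raise ValueError(
            f"max_methylated={rule.max_methylated} must be < CpG count {len(read.calls)}"
        )
    if "N" in read.calls and rule.require_full_coverage:
        return MoleculeClass.EXCLUDED
    n_meth = read.calls.count("M")
    n_unmeth = read.calls.count("U")
    if n_meth <= rule.max_methylated and n_unmeth >= 1:
        return MoleculeClass.UNMETHYLATED
    return MoleculeClass.OTHER


def marker_fraction(
    reads: list[ReadPattern],
    rule: ClassificationRule,
    min_reads: int = 30,
) -> MarkerFraction:
    """Fraction of unmethylated molecules among non-excluded molecules of one marker.

    With no non-excluded reads, the fraction is None (missing), never 0.
    Fractions resting on fewer than ``min_reads`` molecules are flagged
    low-confidence but still reported.
    """
    if not reads:
        raise ValueError("no reads supplied")
    marker_ids = {r.marker_id for r in reads}
    if len(marker_ids) != 1:
        raise ValueError(f"mixed marker_ids: {sorted(marker_ids)}")
    (marker_id,) = marker_ids

    n_kept = 0
    n_unmeth = 0
    for r in reads:
        cls = classify_read(r, rule)
        if cls is MoleculeClass.EXCLUDED:
            continue
        n_kept += 1
        if cls is MoleculeClass.UNMETHYLATED:
            n_unmeth += 1
    fraction = n_unmeth / n_kept if n_kept else None
    return MarkerFraction(
        marker_id=marker_id,
        fraction=fraction,
        n_reads=n_kept,
        n_unmethylated=n_unmeth,
        low_confidence=n_kept < min_reads,
    )


def conversion_qc(
    reads: list[ReadPattern], min_rate: float = 0.98, sample_id: str = ""
) -> ConversionQC:
    """Pooled bisulfite conversion rate over all non-CpG cytosines.

    rate = 1 - sum(unconverted) / sum(total); a sample passes at
    rate >= min_rate. Failing samples are flagged, not dropped.
    """
    total = sum(r.non_cpg_c_total for r in reads)
    unconverted = sum(r.non_cpg_c_unconverted for r in reads)
    if total == 0:
        raise ValueError("no conversion evidence: all non-CpG totals are zero")
    rate = 1.0 - unconverted / total
    return ConversionQC(sample_id=sample_id, conversion_rate=rate, passed=rate >= min_rate)


def ge_per_ml(
    fraction: float, cfdna_ng_per_ml: float, factor: float = GE_PER_NG
) -> float:
    """Cell-type-specific cfDNA concentration: fraction x ng/ml x 303.

    ``factor`` defaults to the printed constant 303; pass ``GE_PER_NG_EXACT``
    for the unrounded 1000/3.3.
    """
    if not (np.isfinite(fraction) and np.isfinite(cfdna_ng_per_ml)):
        raise ValueError("inputs must be finite")
    if fraction < 0 or fraction > 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if cfdna_ng_per_ml < 0:
        raise ValueError("cfDNA concentration must be >= 0")
    return fraction * cfdna_ng_per_ml * factor


def aggregate_cell_type(
    fractions: list[MarkerFraction], method: str = "depth_weighted"
) -> tuple[float | None, str]:
    """Combine per-marker fractions into one cell-type fraction.

    Default is the read-depth-weighted mean over markers with a defined
    fraction; "mean" (unweighted) and "median" are selectable. Returns
    (aggregate, method); aggregate is None when every marker is missing.
    """
    if method not in ("depth_weighted", "mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    vals = [(f.fraction, f.n_reads) for f in fractions if f.fraction is not None]
    if not vals:
        return None, method
    fr = np.array([v for v, _ in vals], dtype=float)
    w = np.array([n for _, n in vals], dtype=float)
    if method == "depth_weighted":
        agg = float(np.average(fr, weights=w)) if w.sum() > 0 else None
    elif method == "mean":
        agg = float(fr.mean())
    else:
        agg = float(np.median(fr))
    return agg, method


def quantify_sample(
    sample_id: str,
    reads_by_marker: dict[str, list[ReadPattern]],
    panel: dict[str, tuple[str, int]],
    cfdna_ng_per_ml: float,
    min_reads: int = 30,
    min_conversion_rate: float = 0.98,
    aggregation: str = "depth_weighted",
    factor: float = GE_PER_NG,
) -> SampleQuant:
    """Full per-sample quantification across a marker panel.

    ``panel`` maps marker_id -> (target_cell_type, max_methylated). Computes
    per-marker unmethylated fractions, aggregates markers of each cell type,
    converts aggregates to GE/ml, and runs sample-level conversion QC.
    """
    marker_fracs: dict[str, MarkerFraction] = {}
    for marker_id, reads in reads_by_marker.items():
        if marker_id not in panel:
            raise ValueError(f"marker {marker_id!r} not in panel")
        _, max_meth = panel[marker_id]
        rule = ClassificationRule(max_methylated=max_meth)
        marker_fracs[marker_id] = marker_fraction(reads, rule, min_reads=min_reads)

    cell_types = sorted({ct for ct, _ in panel.values()})
    ct_fractions: dict[str, float | None] = {}
    ge: dict[str, float | None] = {}
    for ct in cell_types:
        fracs = [
            marker_fracs[m]
            for m in marker_fracs
            if panel[m][0] == ct
        ]
        agg, _ = aggregate_cell_type(fracs, method=aggregation)
        ct_fractions[ct] = agg
        ge[ct] = None if agg is None else ge_per_ml(agg, cfdna_ng_per_ml, factor=factor)

    all_reads = [r for reads in reads_by_marker.values() for r in reads]
    qc = None
    if any(r.non_cpg_c_total > 0 for r in all_reads):
        qc = conversion_qc(all_reads, min_rate=min_conversion_rate, sample_id=sample_id)

    return SampleQuant(
        sample_id=sample_id,
        cfdna_ng_per_ml=cfdna_ng_per_ml,
        marker_fractions=marker_fracs,
        cell_type_fractions=ct_fractions,
        ge_per_ml=ge,
        aggregation_method=aggregation,
        qc=qc,
    )
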