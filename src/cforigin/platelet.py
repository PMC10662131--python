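"""Composition analysis of platelet whole-genome bisulfite sequencing.

Platelets are anucleate, yet carry megakaryocyte-derived genomic DNA alongside
abundant mitochondrial DNA. This module works from post-alignment summaries
(per-chromosome deduplicated proper-pair read counts and a chrom.sizes table):
chromosome representation relative to reference length, mitochondrial DNA
fraction, per-platelet genome content, and the donor-marker (SRY / autosomal
control) chimerism ratio used to follow sex-mismatched platelet transfusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_MT_NAMES = ("chrM", "MT", "chrMT", "M")
#: Haploid human genome mass in picograms.
HAPLOID_GENOME_PG = 3.3
#: Mitochondrial genome size in kb.
MITO_GENOME_KB = 16.569


@dataclass
class ChromCounts:
    """Aligned read counts and reference lengths per chromosome."""

    counts: dict[str, int]
    lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(self.counts) - set(self.lengths)
        if missing:
            raise ValueError(f"chromosomes without a reference length: {sorted(missing)}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("read counts must be >= 0")
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("reference lengths must be > 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def mt_name(self) -> str:
        for name in _MT_NAMES:
            if name in self.counts:
                return name
        raise ValueError(f"no mitochondrial record among {sorted(self.counts)}")


def chromosome_representation(
    counts: ChromCounts, exclude: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Observed vs length-expected fraction and enrichment per chromosome.

    observed = count / total reads; expected = length / total length over the
    chromosomes considered; enrichment = observed / expected. ``exclude``
    removes chromosomes (e.g. Y for female samples, or MT to look at nuclear
    representation only) from both numerator and the expectation. The
    expected-fraction-weighted mean enrichment is 1 by construction.
    """
    names = [c for c in counts.counts if c not in exclude]
    if not names:
        raise ValueError("no chromosomes left after exclusion")
    n = np.array([counts.counts[c] for c in names], dtype=float)
    L = np.array([counts.lengths[c] for c in names], dtype=float)
    if n.sum() == 0:
        raise ValueError("zero total read count")
    observed = n / n.sum()
    expected = L / L.sum()
    enrichment = observed / expected
    return pd.DataFrame(
        {"observed_fraction": observed, "expected_fraction": expected, "enrichment": enrichment},
        index=pd.Index(names, name="chromosome"),
    )


def mito_fraction(counts: ChromCounts) -> float:
    """Fraction of reads mapping to the mitochondrial genome."""
    if counts.total == 0:
        raise ValueError("zero total read count")
    return counts.counts[counts.mt_name()] / counts.total


def genomes_per_platelet(total_dna_ng: float, platelet_count: int) -> float:
    """Haploid genome equivalents of DNA per platelet.

    (ng -> pg, divided by the 3.3 pg haploid genome mass) / platelet count.
    """
    if platelet_count <= 0:
        raise ValueError("platelet_count must be > 0")
    if total_dna_ng < 0:
        raise ValueError("DNA mass must be >= 0")
    return (total_dna_ng * 1000.0 / HAPLOID_GENOME_PG) / platelet_count


def genomic_kb_per_platelet(
    mito_per_platelet: float = 5.0,
    mito_genome_kb: float = MITO_GENOME_KB,
    mito_dna_fraction: float = 0.59,
) -> float:
    """Genomic (nuclear) kb per platelet implied by its mitochondrial content.

    With m mitochondrial genomes per platelet contributing
    mito_kb = m x 16.569 kb, and mitochondrial DNA making up fraction f of
    platelet DNA, the nuclear complement is mito_kb x (1 - f) / f. At the
    defaults (5 mitochondria, f = 0.59) this is ~57.6 kb — an
    order-of-magnitude consistency check on per-platelet genome content.
    """
    f = mito_dna_fraction
    if not (0 < f < 1):
        raise ValueError("mito_dna_fraction must be strictly between 0 and 1")
    if mito_per_platelet < 0 or mito_genome_kb <= 0:
        raise ValueError("invalid mitochondrial parameters")
    mito_kb = mito_per_platelet * mito_genome_kb
    return mito_kb * (1.0 - f) / f


def sry_ratio_timecourse(
    counts: pd.DataFrame,
    copy_number_corrected: bool = False,
) -> pd.DataFrame:
    """Donor-chimerism ratio time course after sex-mismatched transfusion.

    ``counts`` needs columns ``timepoint``, ``sry_count`` (Y-chromosome donor
    marker) and ``control_count`` (autosomal control, e.g. the Beta-actin
    locus). Per timepoint: ratio = SRY / control and detection limit =
    1 / control (the smallest nonzero ratio observable at that depth); zero
    SRY reads give ratio 0 with the limit reported alongside. SRY is
    single-copy per male genome while the autosomal control is two-copy, so
    ``copy_number_corrected`` doubles the raw ratio to a male-genome fraction.
    Timepoints with zero control reads are flagged, never dropped.
    """
    required = {"timepoint", "sry_count", "control_count"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    out = counts.copy()
    ctrl = out["control_count"].to_numpy(dtype=float)
    sry = out["sry_count"].to_numpy(dtype=float)
    flagged = ctrl == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flagged, np.nan, sry / np.where(flagged, 1, ctrl))
        limit = np.where(flagged, np.nan, 1.0 / np.where(flagged, 1, ctrl))
    if copy_number_corrected:
        ratio = ratio * 2.0
    out["ratio"] = ratio
    out["detection_limit"] = limit
    out["flagged"] = flagged
    return out
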