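"""Reference methylation atlas: cell-type-specific CpG and marker-region discovery.

A reference atlas is a collection of per-sample methylomes (one per reference
sample of one cell type). A CpG is *cell-type specific* for a target cell type
when it is unmethylated (beta < ``lo``, default 0.20) in every sample of the
target and methylated (beta > ``hi``, default 0.80) in every sample of every
other cell type — or the mirrored (hypermethylated) criterion. Specific CpGs
that cluster into CpG-dense runs (at least ``min_cpgs`` CpGs spanning at most
``window_bp`` base pairs, defaults 5 within 120 bp) are promoted to assay-grade
marker regions suitable for targeted bisulfite sequencing.

Coordinates are 0-based half-open (BED convention); a CpG position is the
plus-strand C of the strand-collapsed dinucleotide, and a region covering CpGs
at positions p1..pk spans [p1, pk + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HYPO = "hypo"
HYPER = "hyper"
_DIRECTIONS = (HYPO, HYPER)


@dataclass(frozen=True, order=True)
class CpGSite:
    """One strand-collapsed CpG dinucleotide (0-based plus-strand C)."""

    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"CpG position must be >= 0, got {self.position}")


@dataclass
class CellTypeMethylome:
    """Per-CpG methylation levels of one reference sample of one cell type.

    ``beta`` and ``depth`` are pandas Series indexed by (chromosome, position);
    beta is defined only where depth > 0 and lies in [0, 1].
    """

    cell_type: str
    sample_id: str
    beta: pd.Series
    depth: pd.Series

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.depth.index):
            raise ValueError("beta and depth must share one CpG index")
        if len(self.beta) and not self.beta.index.is_monotonic_increasing:
            order = self.beta.index.sortlevel([0, 1])[1]
            self.beta = self.beta.iloc[order]
            self.depth = self.depth.iloc[order]
        if (self.depth <= 0).any():
            raise ValueError("beta defined only where depth > 0")
        bad = (self.beta < 0) | (self.beta > 1)
        if bad.any():
            chrom, pos = self.beta.index[int(np.flatnonzero(bad)[0])]
            raise ValueError(f"beta outside [0, 1] at {chrom}:{pos}")

    @classmethod
    def from_arrays(cls, cell_type, sample_id, chromosomes, positions, beta, depth):
        idx = pd.MultiIndex.from_arrays(
            [np.asarray(chromosomes), np.asarray(positions, dtype=np.int64)],
            names=["chromosome", "position"],
        )
        return cls(
            cell_type,
            sample_id,
            pd.Series(np.asarray(beta, dtype=float), index=idx, name="beta"),
            pd.Series(np.asarray(depth, dtype=np.int64), index=idx, name="depth"),
        )

    @property
    def sites(self) -> list[CpGSite]:
        return [CpGSite(c, int(p)) for c, p in self.beta.index]


@dataclass(frozen=True)
class SelectionThresholds:
    """Marker-selection cutoffs: strict beta < lo (unmethylated) / beta > hi
    (methylated), and region density of min_cpgs CpGs within window_bp."""

    lo: float = 0.20
    hi: float = 0.80
    min_cpgs: int = 5
    window_bp: int = 120

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi < 1):
            raise ValueError("need 0 < lo < hi < 1")
        if self.min_cpgs < 1 or self.window_bp < 1:
            raise ValueError("min_cpgs and window_bp must be >= 1")


@dataclass(frozen=True)
class MarkerRegion:
    """A marker interval with its CpG set, target cell type and direction.

    ``direction`` is the methylation state in the target relative to the
    background: "hypo" (unmethylated in target) or "hyper". Assay-grade regions
    carry >= 5 CpGs within <= 120 bp; regions read back from BED may carry only
    a CpG count (``n_cpgs``) without the site list.
    """

    chromosome: str
    start: int
    end: int
    target_cell_type: str
    direction: str
    cpg_sites: tuple[CpGSite, ...] = ()
    n_cpgs: int = field(default=0)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.start}-{self.end}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}")
        if self.cpg_sites:
            pos = [s.position for s in self.cpg_sites]
            if pos != sorted(pos):
                raise ValueError("cpg_sites must be position-sorted")
            if pos[0] < self.start or pos[-1] + 2 > self.end:
                raise ValueError("cpg_sites outside region interval")
            if any(s.chromosome != self.chromosome for s in self.cpg_sites):
                raise ValueError("cpg_sites on wrong chromosome")
            object.__setattr__(self, "n_cpgs", len(self.cpg_sites))
        elif self.n_cpgs < 1:
            raise ValueError("region must carry >= 1 CpG")

    @property
    def span(self) -> int:
        return self.end - self.start


def _beta_matrix(methylomes: list[CellTypeMethylome]) -> tuple[pd.DataFrame, list[str]]:
    """CpG x sample beta matrix over CpGs covered in every sample."""
    cols = [m.beta.rename(i) for i, m in enumerate(methylomes)]
    mat = pd.concat(cols, axis=1, join="inner")
    return mat, [m.cell_type for m in methylomes]


def select_specific_cpgs(
    methylomes: list[CellTypeMethylome],
    target: str,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[tuple[CpGSite, str]]:
    """Return CpGs specific to ``target``, each tagged "hypo" or "hyper".

    A CpG qualifies as hypo when beta < lo in ALL target samples and
    beta > hi in ALL other samples; hyper is the mirror image. CpGs without
    coverage in any sample are excluded, never imputed. Inequalities are
    strict: beta exactly at a cutoff fails.
    """
    if not methylomes:
        raise ValueError("empty methylomes")
    labels = [m.cell_type for m in methylomes]
    if target not in labels:
        raise ValueError(f"no samples of target cell type {target!r}")
    if all(lbl == target for lbl in labels):
        raise ValueError("background required: need >= 1 non-target sample")

    mat, labels = _beta_matrix(methylomes)
    if mat.empty:
        return []
    is_target = np.array([lbl == target for lbl in labels])
    vals = mat.to_numpy()
    tgt, bg = vals[:, is_target], vals[:, ~is_target]
    lo, hi = thresholds.lo, thresholds.hi
    hypo = (tgt < lo).all(axis=1) & (bg > hi).all(axis=1)
    hyper = (tgt > hi).all(axis=1) & (bg < lo).all(axis=1)

    out: list[tuple[CpGSite, str]] = []
    index = mat.index
    for i in np.flatnonzero(hypo | hyper):
        chrom, pos = index[int(i)]
        out.append((CpGSite(chrom, int(pos)), HYPO if hypo[i] else HYPER))
    out.sort(key=lambda t: (t[0].chromosome, t[0].position))
    return out


def group_cpgs_to_regions(
    specific_cpgs: list[tuple[CpGSite, str]],
    thresholds: SelectionThresholds = SelectionThresholds(),
    target_cell_type: str = "",
) -> list[MarkerRegion]:
    """Group specific CpGs into CpG-dense marker regions.

    Within each maximal run of same-direction specific CpGs on one chromosome,
    every contiguous sub-run with >= min_cpgs CpGs whose footprint
    (last position + 2 - first position) fits within window_bp is a passing
    window; overlapping passing windows are merged, so emitted regions are
    maximal and non-overlapping. Region start is the first CpG position, end
    the last CpG position + 2.
    """
    cpgs = sorted(specific_cpgs, key=lambda t: (t[0].chromosome, t[0].position))
    regions: list[MarkerRegion] = []

    # split into maximal same-chromosome, same-direction runs
    runs: list[list[CpGSite]] = []
    run_dir: list[str] = []
    for site, direction in cpgs:
        if runs and run_dir[-1] == direction and runs[-1][-1].chromosome == site.chromosome:
            runs[-1].append(site)
        else:
            runs.append([site])
            run_dir.append(direction)

    for sites, direction in zip(runs, run_dir):
        pos = [s.position for s in sites]
        n = len(pos)
        # two-pointer: widest window starting at i that fits window_bp
        passing: list[tuple[int, int]] = []
        j = 0
        for i in range(n):
            j = max(j, i)
            while j + 1 < n and pos[j + 1] + 2 - pos[i] <= thresholds.window_bp:
                j += 1
            if j - i + 1 >= thresholds.min_cpgs and pos[j] + 2 - pos[i] <= thresholds.window_bp:
                passing.append((i, j))
        # merge overlapping/adjacent passing index windows into maximal regions
        merged: list[list[int]] = []
        for i, j in passing:
            if merged and i <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], j)
            else:
                merged.append([i, j])
        for i, j in merged:
            members = tuple(sites[i : j + 1])
            regions.append(
                MarkerRegion(
                    chromosome=members[0].chromosome,
                    start=members[0].position,
                    end=members[-1].position + 2,
                    target_cell_type=target_cell_type,
                    direction=direction,
                    cpg_sites=members,
                )
            )
    return regions


def audit_regions(
    regions: list[MarkerRegion], methylomes: list[CellTypeMethylome]
) -> pd.DataFrame:
    """Region x cell-type matrix of mean beta over each region's CpGs.

    Each cell is the unweighted mean beta over the region's covered CpGs,
    averaged across samples of the same cell type; cells with no coverage are
    NaN (missing-flagged), never imputed as 0. Regions hypomethylated in more
    than one column are reported as-is — the audit exists to expose markers
    that cannot distinguish related lineages (e.g. erythroblast loci that are
    also unmethylated in megakaryocytes).
    """
    if not methylomes:
        raise ValueError("empty methylomes")
    for r in regions:
        if not r.cpg_sites and r.n_cpgs < 1:
            raise ValueError("region with zero CpGs")

    cell_types = sorted({m.cell_type for m in methylomes})
    rows = []
    names = []
    for r in regions:
        if not r.cpg_sites:
            raise ValueError(f"region {r.chromosome}:{r.start}-{r.end} lacks CpG sites")
        idx = pd.MultiIndex.from_tuples(
            [(s.chromosome, s.position) for s in r.cpg_sites],
            names=["chromosome", "position"],
        )
        row = {}
        for ct in cell_types:
            sample_means = []
            for m in methylomes:
                if m.cell_type != ct:
                    continue
                covered = m.beta.reindex(idx).dropna()
                sample_means.append(covered.mean() if len(covered) else np.nan)
            row[ct] = float(np.nanmean(sample_means)) if not all(
                np.isnan(v) for v in sample_means
            ) else np.nan
        rows.append(row)
        names.append(f"{r.chromosome}:{r.start}-{r.end}")
    return pd.DataFrame(rows, index=names, columns=cell_types)


def filter_cross_reactive(
    regions: list[MarkerRegion],
    methylomes: list[CellTypeMethylome],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> list[MarkerRegion]:
    """Cross-tissue validation: drop regions that lose specificity against any
    extra methylomes (Roadmap-style check against additional tissues).

    A hypo region is dropped if any non-target cell type's mean beta over the
    region is < hi; a hyper region if any non-target mean is > lo. Cell types
    without coverage over a region do not invalidate it.
    """
    if not regions:
        return []
    audit = audit_regions(regions, methylomes)
    kept = []
    for r, (_, row) in zip(regions, audit.iterrows()):
        others = row.drop(labels=[r.target_cell_type], errors="ignore").dropna()
        if r.direction == HYPO:
            ok = (others >= thresholds.hi).all()
        else:
            ok = (others <= thresholds.lo).all()
        if ok:
            kept.append(r)
    return kept
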