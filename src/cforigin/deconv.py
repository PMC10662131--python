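"""Methylome deconvolution: homogeneous-block segmentation, cell-type-unique
regions, and non-negative least squares (NNLS) mixture estimation with
bootstrap confidence intervals.

The observation unit is the *block*: a run of nearby CpGs whose methylation is
near-constant within every reference sample. Block-level mean betas of the
references form the atlas matrix A (blocks x cell types); a bulk methylome's
block betas b are decomposed by solving min ||A x - b||_2 subject to x >= 0
over the blocks the sample covers, then renormalizing x to the unit simplex.
Confidence intervals come from bootstrapping blocks with replacement and
re-solving per replicate (default 10000 iterations, 90% level); the reported
point estimate of a bootstrap run is the mean across replicates.

The segmenter here is a deliberately simple greedy scan (tolerance on the
departure of each sample's beta from its running block mean, and a maximum
CpG-to-CpG gap); externally produced blocks can equally be supplied as a
BED-like table, and the downstream NNLS is agnostic to the segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .atlas import CellTypeMethylome, CpGSite, MarkerRegion, SelectionThresholds

UNIDENTIFIABLE = "unidentifiable"


@dataclass
class MethylationBlock:
    """A multi-sample homogeneous run of CpGs with per-cell-type mean beta."""

    chromosome: str
    start: int
    end: int
    cpg_sites: tuple[CpGSite, ...]
    cell_type_means: dict[str, float]
    n_cpgs_stored: int = 0  # for blocks loaded without their site list

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("invalid block interval")
        for ct, v in self.cell_type_means.items():
            if not (0 <= v <= 1):
                raise ValueError(f"mean beta for {ct} outside [0,1]")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_sites) or self.n_cpgs_stored


@dataclass
class ReferenceAtlas:
    """Ordered cell types plus the block x cell-type mean-beta matrix A.

    Uninformative blocks (identical across all cell types) carry no mixture
    information and are dropped at construction.
    """

    cell_types: list[str]
    blocks: list[MethylationBlock]
    matrix: np.ndarray  # shape (n_blocks, n_cell_types)

    @classmethod
    def from_blocks(
        cls, blocks: list[MethylationBlock], drop_uninformative: bool = True, atol: float = 1e-12
    ) -> "ReferenceAtlas":
        if not blocks:
            raise ValueError("no blocks")
        cell_types = sorted(blocks[0].cell_type_means)
        rows, kept = [], []
        for b in blocks:
            if sorted(b.cell_type_means) != cell_types:
                raise ValueError("blocks disagree on cell types")
            row = np.array([b.cell_type_means[ct] for ct in cell_types])
            if drop_uninformative and np.ptp(row) <= atol:
                continue
            rows.append(row)
            kept.append(b)
        if not rows:
            raise ValueError("all blocks uninformative")
        return cls(cell_types=cell_types, blocks=kept, matrix=np.vstack(rows))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.cell_types)
        df.insert(0, "chrom", [b.chromosome for b in self.blocks])
        df.insert(1, "start", [b.start for b in self.blocks])
        df.insert(2, "end", [b.end for b in self.blocks])
        df.insert(3, "n_cpgs", [b.n_cpgs for b in self.blocks])
        return df


@dataclass
class DeconvolutionResult:
    """Mixture proportions on the unit simplex, with optional bootstrap CIs."""

    proportions: dict[str, float]
    residual: float
    ci_low: dict[str, float] | None = None
    ci_high: dict[str, float] | None = None
    n_bootstrap: int = 0
    level: float | None = None
    flags: list[str] = field(default_factory=list)


def segment_blocks(
    methylomes: list[CellTypeMethylome],
    tol: float = 0.25,
    max_gap_bp: int = 500,
) -> list[MethylationBlock]:
    """Greedy left-to-right segmentation into multi-sample homogeneous blocks.

    Over CpGs covered in every sample (position-sorted per chromosome), a CpG
    joins the current block iff its distance to the previous CpG is at most
    ``max_gap_bp`` and, for every sample, |beta - running block mean of that
    sample| <= ``tol``. Blocks partition the covered CpGs; the scan is
    deterministic.
    """
    if len(methylomes) < 2:
        raise ValueError("need >= 2 samples to segment")
    mat = pd.concat([m.beta.rename(i) for i, m in enumerate(methylomes)], axis=1, join="inner")
    if mat.empty:
        return []
    order = mat.index.sortlevel([0, 1])[1]
    mat = mat.iloc[order]
    assert mat.index.is_monotonic_increasing

    cell_types = [m.cell_type for m in methylomes]
    chroms = mat.index.get_level_values(0).to_numpy()
    pos = mat.index.get_level_values(1).to_numpy()
    vals = mat.to_numpy()  # (n_cpgs, n_samples)

    blocks: list[MethylationBlock] = []

    def flush(i0: int, i1: int) -> None:
        sites = tuple(CpGSite(chroms[k], int(pos[k])) for k in range(i0, i1))
        sample_means = vals[i0:i1].mean(axis=0)
        means: dict[str, list[float]] = {}
        for ct, mu in zip(cell_types, sample_means):
            means.setdefault(ct, []).append(float(mu))
        ct_means = {ct: float(np.mean(v)) for ct, v in means.items()}
        blocks.append(
            MethylationBlock(
                chromosome=chroms[i0],
                start=int(pos[i0]),
                end=int(pos[i1 - 1]) + 2,
                cpg_sites=sites,
                cell_type_means=ct_means,
            )
        )

    start = 0
    running = vals[0].astype(float).copy()
    for i in range(1, len(pos)):
        n = i - start
        same_chrom = chroms[i] == chroms[start]
        close = same_chrom and (pos[i] - pos[i - 1]) <= max_gap_bp
        homogeneous = close and bool(np.all(np.abs(vals[i] - running / n) <= tol))
        if homogeneous:
            running += vals[i]
        else:
            flush(start, i)
            start = i
            running = vals[i].astype(float).copy()
    flush(start, len(pos))
    return blocks


def unique_regions(
    atlas: ReferenceAtlas, thresholds: SelectionThresholds = SelectionThresholds()
) -> list[MarkerRegion]:
    """Blocks uniquely unmethylated (<lo) or methylated (>hi) in one cell type.

    The block-level analogue of CpG marker selection: a block is unique to a
    cell type when its mean beta is below lo there and above hi in every other
    cell type (hypo), or the mirror (hyper). Blocks low in two cell types at
    once — e.g. erythroblast loci that are also unmethylated in
    megakaryocytes — fail the "all others" clause and are not returned.
    """
    out: list[MarkerRegion] = []
    A = atlas.matrix
    for bi, block in enumerate(atlas.blocks):
        row = A[bi]
        for ci, ct in enumerate(atlas.cell_types):
            others = np.delete(row, ci)
            if row[ci] < thresholds.lo and (others > thresholds.hi).all():
                direction = "hypo"
            elif row[ci] > thresholds.hi and (others < thresholds.lo).all():
                direction = "hyper"
            else:
                continue
            out.append(
                MarkerRegion(
                    chromosome=block.chromosome,
                    start=block.start,
                    end=block.end,
                    target_cell_type=ct,
                    direction=direction,
                    cpg_sites=block.cpg_sites,
                    n_cpgs=max(block.n_cpgs, 1),
                )
            )
    return out


def _solve_simplex_nnls(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    x, rnorm = _scipy_nnls(A, b)
    s = x.sum()
    props = x / s if s > 0 else np.full_like(x, np.nan)
    return props, float(rnorm)


def nnls_deconvolve(
    sample_betas: np.ndarray | pd.Series,
    atlas: ReferenceAtlas,
) -> DeconvolutionResult:
    """Point-estimate NNLS deconvolution of one bulk methylome.

    ``sample_betas`` is a vector over the atlas blocks; NaN marks uncovered
    blocks, which are excluded from the fit. Solves nonnegative least squares
    on covered blocks, renormalizes to proportions summing to 1; the residual
    is the 2-norm of the unnormalized fit. Samples covering fewer blocks than
    cell types, or a rank-deficient covered atlas, yield a result flagged
    "unidentifiable" rather than a silent answer.
    """
    b = np.asarray(sample_betas, dtype=float)
    if b.shape[0] != atlas.matrix.shape[0]:
        raise ValueError("sample vector length must equal atlas block count")
    covered = np.isfinite(b)
    A = atlas.matrix[covered]
    bv = b[covered]
    k = len(atlas.cell_types)
    flags: list[str] = []
    if A.shape[0] < k or np.linalg.matrix_rank(A) < k:
        flags.append(UNIDENTIFIABLE)
    if A.shape[0] == 0:
        return DeconvolutionResult(
            proportions={ct: float("nan") for ct in atlas.cell_types},
            residual=float("nan"),
            flags=flags,
        )
    props, rnorm = _solve_simplex_nnls(A, bv)
    if not np.all(np.isfinite(props)):
        flags.append("degenerate")
    return DeconvolutionResult(
        proportions=dict(zip(atlas.cell_types, (float(p) for p in props))),
        residual=rnorm,
        flags=flags,
    )


def bootstrap_ci(
    sample_betas: np.ndarray | pd.Series,
    atlas: ReferenceAtlas,
    n_iter: int = 10_000,
    level: float = 0.90,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 100,
) -> DeconvolutionResult:
    """Bootstrap deconvolution: resample blocks with replacement, re-solve NNLS.

    The point estimate is the mean proportion across replicates; CIs are the
    empirical (1-level)/2 and 1-(1-level)/2 quantiles. Replicates whose
    resampled atlas is rank-deficient are redrawn (up to ``max_retries`` per
    replicate). Fully reproducible given a seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    b = np.asarray(sample_betas, dtype=float)
    covered = np.isfinite(b)
    A = atlas.matrix[covered]
    bv = b[covered]
    k = len(atlas.cell_types)
    n_blocks = A.shape[0]
    if n_blocks < k:
        raise ValueError("fewer covered blocks than cell types")

    draws = np.empty((n_iter, k))
    for it in range(n_iter):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n_blocks, size=n_blocks)
            Ar = A[idx]
            if np.linalg.matrix_rank(Ar) == k:
                break
        else:
            raise RuntimeError("could not draw a full-rank bootstrap replicate")
        props, _ = _solve_simplex_nnls(Ar, bv[idx])
        draws[it] = props

    point = draws.mean(axis=0)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws, alpha, axis=0)
    hi = np.quantile(draws, 1.0 - alpha, axis=0)
    base = nnls_deconvolve(sample_betas, atlas)
    return DeconvolutionResult(
        proportions=dict(zip(atlas.cell_types, (float(p) for p in point))),
        residual=base.residual,
        ci_low=dict(zip(atlas.cell_types, (float(v) for v in lo))),
        ci_high=dict(zip(atlas.cell_types, (float(v) for v in hi))),
        n_bootstrap=n_iter,
        level=level,
        flags=base.flags,
    )
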