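"""Readers and writers for the interchange formats.

TSV with mandatory headers for tabular data, BED (0-based half-open) for
genomic intervals, JSON for configs and reports. Readers validate and reject
rather than coerce; every writer produces files its paired reader accepts
unchanged.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import CellTypeMethylome, MarkerRegion
from .deconv import MethylationBlock, ReferenceAtlas
from .platelet import ChromCounts
from .targeted import ReadPattern, SampleQuant


class FormatError(ValueError):
    """A malformed input file (validation failure, exit code 2 in the CLI)."""


# ---------------------------------------------------------------------------
# BED


def write_bed(regions: list[MarkerRegion], path: str | Path) -> None:
    """Write marker regions as BED6+1: name=target cell type, score=CpG
    count, strand '.', extra column direction."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chromosome}\t{r.start}\t{r.end}\t{r.target_cell_type}"
                f"\t{r.n_cpgs}\t.\t{r.direction}\n"
            )


def read_bed(path: str | Path) -> list[MarkerRegion]:
    """Read BED6+1 marker regions; CpG site lists are not stored in BED, so
    regions come back with their CpG count only."""
    regions: list[MarkerRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise FormatError(f"{path}:{lineno}: expected 7 BED columns, got {len(parts)}")
            chrom, start_s, end_s, name, score_s, _strand, direction = parts[:7]
            try:
                start, end, score = int(start_s), int(end_s), int(score_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate/score") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            try:
                regions.append(
                    MarkerRegion(
                        chromosome=chrom, start=start, end=end,
                        target_cell_type=name, direction=direction, n_cpgs=score,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return regions


# ---------------------------------------------------------------------------
# methylome tables

_METHYLOME_COLS = ["chrom", "position", "cell_type", "sample_id", "beta", "depth"]


def write_methylome_tsv(methylomes: list[CellTypeMethylome], path: str | Path) -> None:
    frames = []
    for m in methylomes:
        df = pd.DataFrame(
            {
                "chrom": m.beta.index.get_level_values(0),
                "position": m.beta.index.get_level_values(1),
                "cell_type": m.cell_type,
                "sample_id": m.sample_id,
                "beta": m.beta.to_numpy(),
                "depth": m.depth.to_numpy(),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_methylome_tsv(path: str | Path) -> list[CellTypeMethylome]:
    """Read the per-CpG methylome table (one row per CpG per sample)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_METHYLOME_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[(df["beta"] < 0) | (df["beta"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: beta outside [0, 1] at data row {int(bad[0]) + 1}")
    if (df["depth"] <= 0).any():
        row = int(df.index[df["depth"] <= 0][0]) + 1
        raise FormatError(f"{path}: nonpositive depth at data row {row}")
    out = []
    for (ct, sid), sub in df.groupby(["cell_type", "sample_id"], sort=True):
        out.append(
            CellTypeMethylome.from_arrays(
                str(ct), str(sid), sub["chrom"].to_numpy(), sub["position"].to_numpy(),
                sub["beta"].to_numpy(), sub["depth"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# targeted reads and panels

_READS_COLS = ["sample_id", "marker_id", "calls", "non_cpg_total", "non_cpg_unconverted"]


def write_reads_tsv(
    reads_by_sample: dict[str, dict[str, list[ReadPattern]]], path: str | Path
) -> None:
    rows = []
    for sample_id, by_marker in reads_by_sample.items():
        for marker_id, reads in by_marker.items():
            for r in reads:
                rows.append(
                    (sample_id, marker_id, r.calls, r.non_cpg_c_total, r.non_cpg_c_unconverted)
                )
    pd.DataFrame(rows, columns=_READS_COLS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | Path) -> dict[str, dict[str, list[ReadPattern]]]:
    df = pd.read_csv(path, sep="\t", dtype={"calls": str})
    missing = set(_READS_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, dict[str, list[ReadPattern]]] = {}
    for row in df.itertuples(index=True):
        try:
            rp = ReadPattern(
                marker_id=str(row.marker_id),
                calls=str(row.calls),
                non_cpg_c_total=int(row.non_cpg_total),
                non_cpg_c_unconverted=int(row.non_cpg_unconverted),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: data row {row.Index + 1}: {exc}") from exc
        out.setdefault(str(row.sample_id), {}).setdefault(rp.marker_id, []).append(rp)
    return out


def read_panel_json(path: str | Path) -> dict[str, tuple[str, int]]:
    """Panel config: marker_id -> {target_cell_type, max_methylated}."""
    with open(path) as fh:
        raw = json.load(fh)
    panel = {}
    for marker_id, entry in raw.items():
        try:
            panel[marker_id] = (str(entry["target_cell_type"]), int(entry["max_methylated"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad panel entry for {marker_id!r}: {exc}") from exc
    return panel


def write_panel_json(panel: dict[str, tuple[str, int]], path: str | Path) -> None:
    payload = {
        m: {"target_cell_type": ct, "max_methylated": mm} for m, (ct, mm) in panel.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "cfdna_ng_per_ml"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["cfdna_ng_per_ml"] < 0).any():
        raise FormatError(f"{path}: negative cfDNA concentration")
    return df


def write_quant_tsv(quants: list[SampleQuant], path: str | Path) -> None:
    """Per-sample, per-cell-type fractions and GE/ml, with QC columns."""
    rows = []
    for q in quants:
        for ct, frac in q.cell_type_fractions.items():
            rows.append(
                {
                    "sample_id": q.sample_id,
                    "cell_type": ct,
                    "fraction": "" if frac is None else frac,
                    "cfdna_ng_per_ml": q.cfdna_ng_per_ml,
                    "ge_per_ml": "" if q.ge_per_ml[ct] is None else q.ge_per_ml[ct],
                    "aggregation": q.aggregation_method,
                    "conversion_rate": "" if q.qc is None else q.qc.conversion_rate,
                    "conversion_pass": "" if q.qc is None else q.qc.passed,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# deconvolution atlas / sample tables


def write_atlas_tsv(atlas: ReferenceAtlas, path: str | Path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path: str | Path) -> ReferenceAtlas:
    """Block table: chrom, start, end, n_cpgs, then one beta column per cell type."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["chrom", "start", "end", "n_cpgs"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    cell_types = [c for c in df.columns if c not in fixed]
    if not cell_types:
        raise FormatError(f"{path}: no cell-type beta columns")
    betas = df[cell_types].to_numpy(dtype=float)
    if np.any(betas < 0) or np.any(betas > 1):
        row = int(np.argwhere((betas < 0) | (betas > 1))[0][0]) + 1
        raise FormatError(f"{path}: beta outside [0, 1] at data row {row}")
    blocks = []
    for i, row in df.iterrows():
        # placeholder CpG sites: BED-style block input carries counts only
        blocks.append(
            MethylationBlock(
                chromosome=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                cpg_sites=(),
                cell_type_means={ct: float(row[ct]) for ct in cell_types},
                n_cpgs_stored=int(row["n_cpgs"]),
            )
        )
    atlas = ReferenceAtlas.from_blocks(blocks, drop_uninformative=False)
    return atlas


def read_sample_blocks_tsv(path: str | Path, atlas: ReferenceAtlas) -> np.ndarray:
    """Sample block betas aligned to an atlas by (chrom, start, end); blocks
    absent from the sample are NaN (uncovered)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "start", "end", "beta"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if ((df["beta"] < 0) | (df["beta"] > 1)).any():
        raise FormatError(f"{path}: beta outside [0, 1]")
    lookup = {
        (str(r["chrom"]), int(r["start"]), int(r["end"])): float(r["beta"])
        for _, r in df.iterrows()
    }
    b = np.full(len(atlas.blocks), np.nan)
    for i, blk in enumerate(atlas.blocks):
        b[i] = lookup.get((blk.chromosome, blk.start, blk.end), np.nan)
    return b


# ---------------------------------------------------------------------------
# chromosome counts


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def read_chrom_counts(path: str | Path, sizes: dict[str, int]) -> ChromCounts:
    """Two-column TSV chrom, count (samtools idxstats' first two columns also
    parse) joined with a chrom.sizes table."""
    counts = {}
    with open(path) as fh:
        header = fh.readline()
        has_header = not header.split("\t")[1].strip().isdigit() if "\t" in header else True
        lines = [] if has_header else [header]
        lines += fh.readlines()
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>count")
            try:
                counts[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer count") from exc
    counts = {c: k for c, k in counts.items() if c in sizes}
    if not counts:
        raise FormatError(f"{path}: no chromosomes overlap the sizes table")
    return ChromCounts(counts=counts, lengths={c: sizes[c] for c in counts})


def write_chrom_counts(counts: ChromCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tcount\n")
        for c, k in counts.counts.items():
            fh.write(f"{c}\t{k}\n")


def write_chrom_sizes(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, l in lengths.items():
            fh.write(f"{c}\t{l}\n")


# ---------------------------------------------------------------------------
# provenance


def provenance_record(config: dict, seed: int | None) -> dict:
    return {
        "tool": "cforigin",
        "version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": config,
    }


def write_json(payload: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
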