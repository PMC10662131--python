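"""Marker discovery: specific-CpG selection and region grouping against
brute-force oracles, threshold monotonicity, and the region audit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cforigin.atlas import (
    CpGSite,
    MarkerRegion,
    SelectionThresholds,
    audit_regions,
    filter_cross_reactive,
    group_cpgs_to_regions,
    select_specific_cpgs,
)

from conftest import make_methylome


def brute_force_select(methylomes, target, th):
    """Independent per-CpG check of both selection criteria."""
    common = set(methylomes[0].beta.index)
    for m in methylomes[1:]:
        common &= set(m.beta.index)
    out = []
    for chrom, pos in sorted(common):
        tgt = [m.beta[(chrom, pos)] for m in methylomes if m.cell_type == target]
        bg = [m.beta[(chrom, pos)] for m in methylomes if m.cell_type != target]
        if all(b < th.lo for b in tgt) and all(b > th.hi for b in bg):
            out.append((CpGSite(chrom, pos), "hypo"))
        elif all(b > th.hi for b in tgt) and all(b < th.lo for b in bg):
            out.append((CpGSite(chrom, pos), "hyper"))
    return out


def oracle_regions(positions, min_cpgs, window_bp):
    """Exhaustive window enumeration: every contiguous subset with
    count >= min_cpgs and footprint <= window_bp, passing windows merged."""
    n = len(positions)
    passing = []
    for i in range(n):
        for j in range(i + min_cpgs - 1, n):
            if positions[j] + 2 - positions[i] <= window_bp:
                passing.append([i, j])
    merged = []
    for i, j in sorted(passing):
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(positions[i], positions[j] + 2) for i, j in merged]


class TestSelectSpecificCpgs:
    def test_hypo_example_at_stated_thresholds(self):
        ms = [
            make_methylome("MK", "a", [0.19]),
            make_methylome("MK", "b", [0.15]),
            make_methylome("gran", "c", [0.81]),
            make_methylome("mono", "d", [0.95]),
        ]
        sel = select_specific_cpgs(ms, "MK")
        assert len(sel) == 1 and sel[0][1] == "hypo"

    def test_boundary_values_fail_strict_inequalities(self):
        ms = [
            make_methylome("MK", "a", [0.20, 0.10]),
            make_methylome("gran", "b", [0.90, 0.80]),
        ]
        assert select_specific_cpgs(ms, "MK") == []

    def test_uniform_half_methylation_selects_nothing(self):
        ms = [make_methylome(ct, ct, [0.5] * 5) for ct in ("MK", "ery", "gran")]
        assert select_specific_cpgs(ms, "MK") == []

    def test_matches_brute_force_oracle(self, rng):
        ms = []
        for ct in ("MK", "ery", "gran"):
            for s in range(2):
                ms.append(make_methylome(ct, f"{ct}{s}", rng.uniform(0, 1, 200)))
        th = SelectionThresholds(lo=0.4, hi=0.6)  # loose cutoffs so hits occur
        got = select_specific_cpgs(ms, "MK", th)
        assert got == brute_force_select(ms, "MK", th)
        assert len(got) > 0

    def test_uncovered_cpgs_are_excluded_not_guessed(self):
        full = make_methylome("MK", "a", [0.1, 0.1])
        partial = make_methylome("gran", "b", [0.9], positions=[0])
        sel = select_specific_cpgs([full, partial], "MK")
        assert [s.position for s, _ in sel] == [0]

    def test_idempotent_under_repeat(self, toy_methylomes):
        th = SelectionThresholds(lo=0.45, hi=0.55)
        first = select_specific_cpgs(toy_methylomes, "MK", th)
        assert select_specific_cpgs(toy_methylomes, "MK", th) == first

    def test_background_required(self):
        ms = [make_methylome("MK", "a", [0.1])]
        with pytest.raises(ValueError, match="background required"):
            select_specific_cpgs(ms, "MK")

    def test_empty_methylomes_error(self):
        with pytest.raises(ValueError):
            select_specific_cpgs([], "MK")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        betas=st.lists(
            st.tuples(st.floats(0.01, 0.99), st.floats(0.01, 0.99)),
            min_size=3, max_size=15,
        ),
        lo=st.floats(0.05, 0.45),
        hi=st.floats(0.55, 0.95),
        dlo=st.floats(0.0, 0.2),
        dhi=st.floats(0.0, 0.2),
    )
    def test_tightening_thresholds_never_grows_selection(self, betas, lo, hi, dlo, dhi):
        ms = [
            make_methylome("MK", "a", [b[0] for b in betas]),
            make_methylome("gran", "b", [b[1] for b in betas]),
        ]
        loose = select_specific_cpgs(ms, "MK", SelectionThresholds(lo=lo, hi=hi))
        lo2 = max(min(lo - dlo, hi - 0.05), 0.01)
        hi2 = min(hi + dhi, 0.99)
        tight = select_specific_cpgs(ms, "MK", SelectionThresholds(lo=lo2, hi=hi2))
        assert set(tight) <= set(loose)


class TestGroupCpgsToRegions:
    def test_five_cpgs_within_window(self):
        cpgs = [(CpGSite("chr1", p), "hypo") for p in (100, 120, 140, 160, 180)]
        regions = group_cpgs_to_regions(cpgs, target_cell_type="MK")
        assert len(regions) == 1
        r = regions[0]
        assert (r.chromosome, r.start, r.end, r.n_cpgs) == ("chr1", 100, 182, 5)
        assert r.direction == "hypo" and r.target_cell_type == "MK"

    def test_four_cpgs_below_density_emit_nothing(self):
        cpgs = [(CpGSite("chr1", p), "hypo") for p in (100, 120, 140, 160)]
        assert group_cpgs_to_regions(cpgs) == []

    def test_seven_cpgs_spanning_150bp_match_window_oracle(self):
        positions = [0, 25, 50, 75, 100, 125, 150]
        cpgs = [(CpGSite("chr1", p), "hypo") for p in positions]
        regions = group_cpgs_to_regions(cpgs)
        expect = oracle_regions(positions, 5, 120)
        assert [(r.start, r.end) for r in regions] == expect

    def test_random_instances_match_window_oracle(self, rng):
        th = SelectionThresholds()
        for _ in range(25):
            positions = np.unique(rng.integers(0, 2000, size=rng.integers(1, 40)))
            cpgs = [(CpGSite("chr2", int(p)), "hypo") for p in positions]
            got = [(r.start, r.end) for r in group_cpgs_to_regions(cpgs, th)]
            assert got == oracle_regions(list(map(int, positions)), th.min_cpgs, th.window_bp)

    def test_direction_change_breaks_runs(self):
        pos = [0, 20, 40, 60, 80, 100, 120, 140, 160, 180]
        cpgs = [(CpGSite("chr1", p), "hypo" if i < 5 else "hyper") for i, p in enumerate(pos)]
        regions = group_cpgs_to_regions(cpgs)
        assert {(r.direction, r.start) for r in regions} == {("hypo", 0), ("hyper", 100)}

    def test_emitted_regions_satisfy_invariants_and_do_not_overlap(self, rng):
        positions = np.unique(rng.integers(0, 5000, size=120))
        cpgs = [(CpGSite("chr3", int(p)), "hypo") for p in positions]
        regions = group_cpgs_to_regions(cpgs)
        assert regions
        for r in regions:
            assert r.n_cpgs >= 5
            assert r.start == r.cpg_sites[0].position
            assert r.end == r.cpg_sites[-1].position + 2
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start

    def test_empty_input_gives_empty_output(self):
        assert group_cpgs_to_regions([]) == []


class TestAuditRegions:
    def test_clean_marker_row(self):
        region = MarkerRegion("chr1", 0, 52, "MK", "hypo",
                              cpg_sites=tuple(CpGSite("chr1", p) for p in (0, 25, 50)))
        ms = [
            make_methylome("MK", "a", [0.0, 0.0, 0.0]),
            make_methylome("gran", "b", [1.0, 1.0, 1.0]),
        ]
        audit = audit_regions([region], ms)
        assert audit.loc[:, "MK"].iloc[0] == 0.0
        assert audit.loc[:, "gran"].iloc[0] == 1.0

    def test_matches_hand_arithmetic_across_samples(self):
        r1 = MarkerRegion("chr1", 0, 27, "MK", "hypo",
                          cpg_sites=(CpGSite("chr1", 0), CpGSite("chr1", 25)))
        r2 = MarkerRegion("chr1", 50, 77, "MK", "hypo",
                          cpg_sites=(CpGSite("chr1", 50), CpGSite("chr1", 75)))
        ms = [
            make_methylome("MK", "a", [0.1, 0.3, 0.5, 0.7]),
            make_methylome("MK", "b", [0.2, 0.4, 0.6, 0.8]),
            make_methylome("gran", "c", [1.0, 0.0, 1.0, 0.0]),
        ]
        audit = audit_regions([r1, r2], ms)
        # per-sample region means, then mean across same-cell-type samples
        assert audit.iloc[0]["MK"] == pytest.approx((0.2 + 0.3) / 2)
        assert audit.iloc[1]["MK"] == pytest.approx((0.6 + 0.7) / 2)
        assert audit.iloc[0]["gran"] == pytest.approx(0.5)

    def test_shared_hypomethylation_is_reported_not_suppressed(self):
        """A region unmethylated in both erythroblasts and megakaryocytes must
        surface in both columns so non-specific markers are exposed."""
        region = MarkerRegion("chr1", 0, 27, "erythroblast", "hypo",
                              cpg_sites=(CpGSite("chr1", 0), CpGSite("chr1", 25)))
        ms = [
            make_methylome("erythroblast", "a", [0.02, 0.02]),
            make_methylome("MK", "b", [0.05, 0.05]),
            make_methylome("gran", "c", [0.95, 0.95]),
        ]
        audit = audit_regions([region], ms)
        assert audit.iloc[0]["MK"] < 0.2 and audit.iloc[0]["erythroblast"] < 0.2
        kept = filter_cross_reactive([region], ms)
        assert kept == []  # cross-reactive marker dropped by the validation filter

    def test_missing_coverage_is_nan_not_zero(self):
        region = MarkerRegion("chr1", 1000, 1027, "MK", "hypo",
                              cpg_sites=(CpGSite("chr1", 1000), CpGSite("chr1", 1025)))
        ms = [
            make_methylome("MK", "a", [0.1, 0.1], positions=[1000, 1025]),
            make_methylome("gran", "b", [0.9], positions=[0]),
        ]
        audit = audit_regions([region], ms)
        assert np.isnan(audit.iloc[0]["gran"])
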