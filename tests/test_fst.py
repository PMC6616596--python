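"""FST scan: per-SNP ANOVA estimates, outliers, regions, annotation."""

import numpy as np
import pytest

import popscan as ps
from popscan.fst import AnnotationInterval, SelectionRegion
from popscan.panel import MISSING, PanelError

from conftest import make_panel, random_panel
from oracles import oracle_fst, oracle_outlier_flags


def test_no_between_group_variance_gives_nonpositive_fst():
    block = np.array([[0], [1], [1], [2]], dtype=np.int8)
    panel = make_panel(np.vstack([block, block]),
                       populations=["A"] * 4 + ["B"] * 4)
    fst = ps.per_snp_fst(panel).table["fst"].to_numpy()
    assert fst[0] <= 0


def test_opposite_fixation_gives_fst_one():
    panel = make_panel(
        np.array([[0], [0], [0], [2], [2], [2]], dtype=np.int8),
        populations=["A"] * 3 + ["B"] * 3)
    assert ps.per_snp_fst(panel).table["fst"].iloc[0] == pytest.approx(1.0)


def test_matches_brute_force_anova(rng):
    panel = random_panel(rng, n=24, m=50, missing_rate=0.08, n_pops=4)
    got = ps.per_snp_fst(panel).table["fst"].to_numpy()
    want = oracle_fst(panel.dosage, panel.samples["population"].tolist())
    assert np.allclose(got, want, atol=1e-10, equal_nan=True)


def test_invariant_to_sample_order_and_allele_flip(rng):
    panel = random_panel(rng, n=20, m=30, missing_rate=0.05, n_pops=2)
    base = ps.per_snp_fst(panel).table["fst"].to_numpy()

    perm = rng.permutation(panel.n_samples)
    shuffled = make_panel(panel.dosage[perm],
                          positions=panel.markers["position"].to_numpy(),
                          populations=[panel.samples["population"][i]
                                       for i in perm])
    assert np.allclose(ps.per_snp_fst(shuffled).table["fst"], base,
                       atol=1e-12, equal_nan=True)

    flipped_d = panel.dosage.copy()
    obs = flipped_d != MISSING
    flipped_d = np.where(obs, 2 - flipped_d, MISSING).astype(np.int8)
    flipped = make_panel(flipped_d,
                         positions=panel.markers["position"].to_numpy(),
                         populations=panel.samples["population"].tolist())
    assert np.allclose(ps.per_snp_fst(flipped).table["fst"], base,
                       atol=1e-12, equal_nan=True)


def _multilocus_theta(dosage, labels):
    """Ratio-of-sums multilocus FST (the standard low-bias combination)."""
    groups = sorted(set(labels))
    num = den = 0.0
    for j in range(dosage.shape[1]):
        sizes, freqs = [], []
        for g in groups:
            col = [dosage[i, j] for i, l in enumerate(labels)
                   if l == g and dosage[i, j] != MISSING]
            if col:
                sizes.append(2 * len(col))
                freqs.append(sum(col) / (2 * len(col)))
        r = len(sizes)
        if r < 2:
            continue
        n_tot = sum(sizes)
        pbar = sum(s * p for s, p in zip(sizes, freqs)) / n_tot
        msp = sum(s * (p - pbar) ** 2
                  for s, p in zip(sizes, freqs)) / (r - 1)
        msg = sum(s * p * (1 - p)
                  for s, p in zip(sizes, freqs)) / (n_tot - r)
        nc = (n_tot - sum(s * s for s in sizes) / n_tot) / (r - 1)
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num / den


def test_drift_divergence_matches_theory():
    """4 demes split t generations ago: FST ≈ 1 - (1 - 1/(2N))^t.

    Uses the multilocus ratio-of-sums combination (per-SNP ratios carry
    a small Jensen bias) averaged over seeds to tame linked-locus noise.
    """
    n_gen, size = 30, 100
    expected = 1 - (1 - 1 / (2 * size)) ** n_gen
    thetas = []
    for seed in (5, 6, 7):
        demo = ps.DemographyConfig(
            populations=[ps.PopulationConfig("A", [size] * (n_gen + 1))] + [
                ps.PopulationConfig(lab, [size] * n_gen)
                for lab in ("B", "C", "D")],
            split_events=[ps.SplitEvent(n_gen, "A", lab)
                         for lab in ("B", "C", "D")],
            sample_sizes={lab: 50 for lab in "ABCD"},
        )
        panel = ps.simulate(demo, ps.GenomeConfig(
            chromosome_length_bp=30_000_000, n_snps=2000, seed=seed))
        thetas.append(_multilocus_theta(
            panel.dosage, panel.samples["population"].tolist()))
    assert np.mean(thetas) == pytest.approx(expected, abs=0.02)


def test_panmictic_99th_percentile_shrinks_with_n():
    """Random group labels on one population: the FST tail -> 0 as n grows."""
    q99 = []
    for n_per in (10, 40, 160):
        demo = ps.constant_demography("P", 4 * n_per, 5, 4 * n_per)
        panel = ps.simulate(demo, ps.GenomeConfig(
            chromosome_length_bp=10_000_000, n_snps=1500, seed=9))
        groups = {iid: f"G{i % 4}" for i, iid in
                  enumerate(panel.samples["individual_id"])}
        fst = ps.per_snp_fst(panel, grouping=groups).table["fst"]
        q99.append(np.nanquantile(fst, 0.99))
    assert q99[0] > q99[1] > q99[2]


# ---------------------------------------------------------- outliers


def test_top_one_percent_arithmetic(rng):
    m = 34_709
    vals = rng.uniform(0, 1, size=m)
    panel_like = _fst_result(vals, rng)
    out = ps.call_outliers(panel_like, quantile=0.99)
    assert int(out.table["significant"].sum()) == 347


def _fst_result(vals, rng):
    import pandas as pd
    from popscan.fst import FstResult
    m = len(vals)
    return FstResult(table=pd.DataFrame({
        "marker_id": [f"s{i}" for i in range(m)],
        "chromosome": rng.integers(1, 19, size=m).astype(str),
        "position": rng.integers(1, 150_000_000, size=m),
        "fst": vals,
    }))


def test_hundred_distinct_values_flags_only_maximum(rng):
    vals = np.linspace(0, 0.9, 100)
    out = ps.call_outliers(_fst_result(vals, rng), quantile=0.99)
    sig = out.table[out.table["significant"]]
    assert len(sig) == 1
    assert sig["fst"].iloc[0] == pytest.approx(0.9)
    assert out.threshold == pytest.approx(0.9)


def test_outlier_flags_match_sort_and_slice(rng):
    vals = rng.uniform(0, 1, size=2000)
    vals[rng.integers(0, 2000, size=20)] = np.nan
    res = _fst_result(vals, rng)
    out = ps.call_outliers(res, quantile=0.95)
    got = set(np.flatnonzero(out.table["significant"].to_numpy()))
    want = oracle_outlier_flags(
        out.table["fst"].to_numpy(), out.table["chromosome"],
        out.table["position"], 0.95)
    assert got == want
    assert len(got) == int(np.floor(0.05 * np.isfinite(vals).sum()))


# ----------------------------------------------------------- regions


def test_region_arithmetic_and_clipping(rng):
    vals = np.zeros(200)
    vals[[0, 1]] = [0.9, 0.8]
    res = _fst_result(vals, rng)
    res.table.loc[0, ["chromosome", "position"]] = ["1", 149_872_523]
    res.table.loc[1, ["chromosome", "position"]] = ["2", 100_000]
    out = ps.call_outliers(res, quantile=0.99)
    regions = ps.build_regions(out)
    by_id = {r.snp_id: r for r in regions}
    assert len(regions) == 2
    r0 = by_id["s0"]
    assert (r0.start, r0.end) == (149_672_523, 150_072_523)
    r1 = by_id["s1"]
    assert (r1.start, r1.end) == (1, 300_000)  # clipped at chromosome start


def test_one_region_per_significant_snp(rng):
    vals = rng.uniform(0, 1, size=34_709)
    out = ps.call_outliers(_fst_result(vals, rng), quantile=0.99)
    assert len(ps.build_regions(out)) == 347


# -------------------------------------------------------- annotation


def test_overlap_boundary_conventions():
    regions = [SelectionRegion("1", 1000, 2000, "s", 0.9)]
    abutting = [AnnotationInterval("1", 2001, 2500, "after")]
    containing = [AnnotationInterval("1", 500, 5000, "around")]
    assert ps.overlap_annotation(regions, abutting).empty
    hit = ps.overlap_annotation(regions, containing)
    assert list(hit["name"]) == ["around"]
    touch = [AnnotationInterval("1", 2000, 2500, "edge")]
    assert list(ps.overlap_annotation(regions, touch)["name"]) == ["edge"]


def test_overlap_matches_double_loop(rng):
    regions = [
        SelectionRegion(str(rng.integers(1, 4)),
                        int(p := rng.integers(1, 10_000)), int(p + 400),
                        f"r{i}", 0.5)
        for i in range(10)
    ]
    intervals = [
        AnnotationInterval(str(rng.integers(1, 4)),
                           int(s := rng.integers(1, 10_000)),
                           int(s + rng.integers(10, 500)), f"iv{j}")
        for j in range(20)
    ]
    got = ps.overlap_annotation(regions, intervals)
    expected = set()
    for r in regions:
        for iv in intervals:
            if r.chromosome == iv.chromosome and \
                    r.start <= iv.end and iv.start <= r.end:
                expected.add((r.snp_id, iv.name))
    assert set(zip(got["snp_id"], got["name"])) == expected


def test_bed_round_trip_conventions(tmp_path):
    bed = tmp_path / "ann.bed"
    bed.write_text("1\t999\t2000\tgeneA\n2\t0\t100\tgeneB\n")
    ann = ps.read_annotation_bed(bed)
    assert (ann[0].start, ann[0].end) == (1000, 2000)  # 0-based -> 1-based
    assert (ann[1].start, ann[1].end) == (1, 100)

    regions = [SelectionRegion("1", 1000, 2000, "s", 0.9)]
    out = tmp_path / "regions.bed"
    ps.regions_to_bed(regions, out)
    assert out.read_text().split("\t")[:3] == ["1", "999", "2000"]


def test_malformed_bed_line_reports_line_number(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("1\t100\t200\tok\n1\tnope\t300\tbad\n")
    with pytest.raises(PanelError, match="line 2"):
        ps.read_annotation_bed(bed)
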