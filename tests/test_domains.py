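"""Window enrichment, island calling, centromere assembly, depletion test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import cenchrom as cc
from cenchrom.domains import (
    DepletedParams,
    IslandParams,
    assemble_centromeres,
    call_depleted,
    call_islands,
    count_midpoints,
    depletion_pvalues,
    summarize_subdomains,
    window_enrichment,
)
from cenchrom.intervals import as_intervals

from conftest import make_fragments


def uniform_fragments(rng, n, size=1_000_000, chrom="c"):
    mids = rng.integers(80, size - 80, n)
    return make_fragments(mids, chrom=chrom)


# ------------------------------------------------------------- enrichment
def test_enrichment_exact_ratio_eps_zero(rng):
    # equal library sizes; chip_w=90, input_w=30 in the first window -> 3.0
    chip = make_fragments(np.concatenate([np.full(90, 500), rng.integers(10_500, 99_000, 910)]))
    inp = make_fragments(np.concatenate([np.full(30, 500), rng.integers(10_500, 99_000, 970)]))
    wt = window_enrichment(chip, inp, {"chr1": 100_000}, window=10_000, eps=0)
    assert wt["enrichment"].iloc[0] == pytest.approx(3.0)


def test_enrichment_zero_chip_window(rng):
    chip = make_fragments(rng.integers(10_500, 99_000, 500))
    inp = make_fragments(rng.integers(80, 99_000, 500))
    wt = window_enrichment(chip, inp, {"chr1": 100_000}, window=10_000)
    assert wt["enrichment"].iloc[0] == 0.0


def test_enrichment_fold_recovered_from_generator():
    # per-kb chip/input ratio approaches the planted fold when centromeres are
    # a small genome fraction (the real-genome regime)
    cfg = cc.GeneratorConfig(
        n_chromosomes=1, chrom_length=30_000_000, chrom_names=["c"],
        centromere_intervals=[("c", 15_000_000, 15_050_000)],
        unique_fraction_centromere=1.0, background_fraction=0.0, seed=8,
    )
    m = cc.plant_nucleosomes(cc.generate_genome(cfg))
    chip = cc.simulate_library(m, "chip", 1_000_000)
    inp = cc.simulate_library(m, "input", 1_000_000)

    def perkb(fs):
        mid = fs.midpoints
        return ((mid >= 15_000_000) & (mid < 15_050_000)).sum() / 50.0

    ratio = perkb(chip) / perkb(inp)
    assert ratio == pytest.approx(30.0, rel=0.10)


# ------------------------------------------------------------- islands
def brute_force_islands(chip_counts, input_counts, n_chip, n_input, genome, params):
    """Independent python-loop island enumerator (same definition, no vectorization)."""
    lam_bg = n_chip * params.window / (params.effective_genome_fraction * genome)
    scale = n_chip / max(n_input, 1)
    eligible = []
    for i, c in enumerate(chip_counts):
        lam = max(input_counts[i] * scale, lam_bg)
        p = poisson.sf(c - 1, lam)
        if p < params.eligible_p and c > 0:
            eligible.append(i)
    groups = []
    for i in eligible:
        if groups and i - groups[-1][-1] <= params.gap // params.window + 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [(g[0] * params.window, (g[-1] + 1) * params.window) for g in groups]


def test_gap_rule_splits_islands(rng):
    # two enriched windows separated by 4 kb of ineligible windows -> two islands
    params = IslandParams()
    bg = uniform_fragments(rng, 30_000, 100_000)
    spike1 = make_fragments(np.full(300, 10_500), chrom="c")
    spike2 = make_fragments(np.full(300, 15_500), chrom="c")
    fs = cc.FragmentSet.concat([bg, spike1, spike2])
    inp = uniform_fragments(rng, 30_000, 100_000)
    isl = call_islands(fs, inp, {"c": 100_000}, params)
    assert len(isl) == 2
    # 3 kb separation (== gap) merges them instead
    spike2b = make_fragments(np.full(300, 14_500), chrom="c")
    isl2 = call_islands(cc.FragmentSet.concat([bg, spike1, spike2b]), inp, {"c": 100_000}, params)
    assert len(isl2) == 1


def test_islands_match_brute_force_enumerator(rng):
    params = IslandParams()
    for trial in range(3):
        n = 40_000
        mids = rng.integers(80, 999_920, n)
        # plant two enriched patches
        mids[:2000] = rng.integers(200_000, 210_000, 2000)
        mids[2000:3000] = rng.integers(650_000, 654_000, 1000)
        chip = make_fragments(mids, chrom="c")
        inp = uniform_fragments(rng, n, 1_000_000)
        isl = call_islands(chip, inp, {"c": 1_000_000}, params)
        cc_counts = count_midpoints(chip, {"c": 1_000_000}, params.window)["c"]
        ic_counts = count_midpoints(inp, {"c": 1_000_000}, params.window)["c"]
        want = brute_force_islands(cc_counts, ic_counts, len(chip), len(inp), 1_000_000, params)
        got_spans = [tuple(x) for x in isl[["start", "end"]].to_numpy()]
        # the caller additionally applies the significance filter; every called
        # island must be an enumerated span, and the planted patches must survive
        assert set(got_spans) <= set(want)
        assert any(s <= 200_000 and e >= 210_000 for s, e in got_spans)


def test_null_uniform_data_yields_no_islands(rng):
    hits = 0
    for seed in range(40):
        r = np.random.default_rng([41, seed])
        chip = uniform_fragments(r, 20_000)
        inp = uniform_fragments(r, 20_000)
        hits += len(call_islands(chip, inp, {"c": 1_000_000})) > 0
    assert hits <= 2  # >= 95% of seeds clean


def test_planted_domain_recovered_as_single_island():
    cfg = cc.GeneratorConfig(
        n_chromosomes=1, chrom_length=2_000_000, chrom_names=["c"],
        centromere_intervals=[("c", 1_000_000, 1_100_000)],
        unique_fraction_centromere=1.0, seed=7,
    )
    m = cc.plant_nucleosomes(cc.generate_genome(cfg))
    chip = cc.simulate_library(m, "chip", 100_000)
    inp = cc.simulate_library(m, "input", 100_000)
    isl = call_islands(chip, inp, m.chrom_sizes)
    assert len(isl) == 1
    s, e = isl.iloc[0]["start"], isl.iloc[0]["end"]
    covered = max(0, min(e, 1_100_000) - max(s, 1_000_000))
    assert covered >= 0.9 * 100_000


# ------------------------------------------------------------- assembly
def test_assembly_merge_and_size_rules():
    isl = as_intervals([("c", 0, 40_000), ("c", 120_000, 160_000)])
    out = assemble_centromeres(isl)
    assert len(out) == 1 and out.iloc[0]["end"] == 160_000  # 80-kb gap < 100 kb merges
    small = as_intervals([("c", 0, 25_000)])
    assert len(assemble_centromeres(small)) == 0  # < 30 kb discarded
    assert len(assemble_centromeres(as_intervals([]))) == 0


# ------------------------------------------------------------- depletion
def test_depletion_pvalue_closed_form():
    p = depletion_pvalues(np.array([0]), np.array([15]), 1.0)[0]
    assert p == pytest.approx(np.exp(-15), rel=1e-12)
    assert p < 1e-5
    # typical window chip == lambda -> clearly not depleted
    p_typ = depletion_pvalues(np.array([100]), np.array([100]), 1.0)[0]
    assert p_typ > 0.4


def test_depleted_self_test_false_positive_bound(rng):
    # chip == input (self-test): expected false positives <= 1e-5 * n windows
    counts = rng.poisson(30, 1_000_000)
    p = depletion_pvalues(counts, counts, 1.0)
    assert (p < 1e-5).sum() <= 5


def test_edge_windows_discarded(rng):
    # a strongly depleted candidate 150 kb from the centromere end is dropped
    size = 1_000_000
    cen = as_intervals([("c", 0, size)])
    win = []
    for s in range(0, size, 10_000):
        win.append(("c", s, s + 10_000, 1.0, True))
    wt = pd.DataFrame(win, columns=["chrom", "start", "end", "mappable_frac", "mappable"])
    mids = rng.integers(80, size - 80, 200_000)
    hole_edge = (mids < 150_000) | (mids >= 160_000)  # depleted window at 150 kb
    hole_mid = (mids < 500_000) | (mids >= 510_000)  # depleted window at 500 kb
    chip = make_fragments(mids[hole_edge & hole_mid], chrom="c")
    inp = make_fragments(rng.integers(80, size - 80, 200_000), chrom="c")
    dep = call_depleted(chip, inp, cen, wt)
    spans = [tuple(x) for x in dep[["start", "end"]].to_numpy()]
    assert (500_000, 510_000) in spans
    assert all(s >= 200_000 and e <= size - 200_000 for s, e in spans)


def test_summary_zero_depleted():
    cen = as_intervals([("c", 0, 100_000)])
    cen["name"] = "cen_c"
    wt = pd.DataFrame(
        [("c", s, s + 10_000, 1.0, True) for s in range(0, 100_000, 10_000)],
        columns=["chrom", "start", "end", "mappable_frac", "mappable"],
    )
    tab = summarize_subdomains(pd.DataFrame(columns=["chrom", "start", "end"]), cen, wt)
    total = tab.iloc[-1]
    assert total["depleted_kb"] == 0 and total["depleted_pct"] == 0
    assert total["enriched_pct"] == 100.0


def test_depleted_and_enriched_partition_mappable(minimal_model):
    model = minimal_model
    chip = cc.simulate_library(model, "chip", 400_000)
    inp = cc.simulate_library(model, "input", 400_000)
    from cenchrom.mappability import mappable_windows, unique_kmer_mask

    wt = mappable_windows(unique_kmer_mask(model.sequences, k=50), model.chrom_sizes)
    cens = model.features["centromeres"]
    dep = call_depleted(chip, inp, cens, wt)
    tab = summarize_subdomains(dep, cens, wt)
    assert np.allclose(tab["depleted_pct"] + tab["enriched_pct"], 100.0)
    # the planted 100-kb subdomain is recovered
    assert tab.iloc[-1]["depleted_kb"] == pytest.approx(100.0, abs=15)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IslandParams(window=1000, gap=2500)
    with pytest.raises(ValueError):
        DepletedParams(window=0)
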