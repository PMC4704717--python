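"""Generator invariants: geometry, determinism, planted-truth bookkeeping."""

import filecmp

import numpy as np
import pytest

import cenchrom as cc
from cenchrom.synth import MAIZE_CEN_LENGTHS_MB, MAIZE_DEPLETED_KB, maize_preset


def small_config(**kw):
    defaults = dict(
        n_chromosomes=1,
        chrom_length=5_000_000,
        chrom_names=["chr1"],
        centromere_intervals=[("chr1", 1_800_000, 3_200_000)],
        satellite_arrays=[("chr1", 2_000_000, 200)],
        unique_fraction_centromere=1.0,
        seed=0,
    )
    defaults.update(kw)
    return cc.GeneratorConfig(**defaults)


# ------------------------------------------------------------- geometry
def test_array_span_arithmetic():
    cfg = small_config()
    model = cc.generate_genome(cfg)
    arr = model.features["arrays"].iloc[0]
    assert (arr["start"], arr["end"]) == (2_000_000, 2_031_200)  # 200 x 156
    # sequence at the array is exact tandem copies
    s = model.sequence_str("chr1")
    assert s[2_000_000 : 2_000_156] == cfg.satellite_monomer
    assert s[2_031_044 : 2_031_200] == cfg.satellite_monomer


def test_overlapping_planted_intervals_rejected():
    cfg = small_config(depleted_subdomains=[("chr1", 2_030_000, 2_080_000)])  # overlaps array
    with pytest.raises(ValueError, match="overlap"):
        cc.generate_genome(cfg)


def test_interval_outside_chromosome_rejected():
    with pytest.raises(ValueError, match="outside"):
        cc.generate_genome(small_config(centromere_intervals=[("chr1", 4_000_000, 6_000_000)]))


def test_maize_preset_centromere_lengths():
    model = cc.generate_genome(maize_preset(seed=0))
    assert model.truth["centromere_lengths_mb"] == MAIZE_CEN_LENGTHS_MB
    assert model.truth["depleted_total_kb"] == sum(MAIZE_DEPLETED_KB)


def test_depleted_bookkeeping_matches_interval_arithmetic():
    model = cc.generate_genome(maize_preset(seed=3))
    dep = model.features["depleted"]
    assert (dep["end"] - dep["start"]).sum() / 1e3 == model.truth["depleted_total_kb"]


# ------------------------------------------------------------- determinism
def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = small_config(chrom_length=500_000, centromere_intervals=[("chr1", 100_000, 400_000)],
                       satellite_arrays=[("chr1", 150_000, 50)],
                       unique_fraction_centromere=0.8, seed=11)
    for d in ("a", "b"):
        model = cc.plant_nucleosomes(cc.generate_genome(small_config(
            chrom_length=500_000, centromere_intervals=[("chr1", 100_000, 400_000)],
            satellite_arrays=[("chr1", 150_000, 50)], unique_fraction_centromere=0.8, seed=11)))
        cc.write_truth(model, tmp_path / d)
        cc.simulate_library(model, "chip", 5_000).to_bed(tmp_path / d / "chip.bed")
    for f in ("genome.fa", "truth.json", "depleted.bed", "chip.bed", "duplications.bed"):
        assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f


# ------------------------------------------------------------- nucleosomes
def test_zero_jitter_exact_spacings():
    cfg = small_config(chrom_length=100_000, centromere_intervals=[("chr1", 10_000, 90_000)],
                       satellite_arrays=[("chr1", 20_000, 3)],
                       spacing_jitter_sd=0, phasing_jitter_sd=0)
    model = cc.plant_nucleosomes(cc.generate_genome(cfg))
    nuc = model.nucleosomes
    arr = np.sort(nuc.loc[nuc["in_array"], "mid"].to_numpy())
    assert list(np.diff(arr)) == [156, 156]
    non = np.sort(nuc.loc[~nuc["in_array"], "mid"].to_numpy())
    gaps = np.diff(non)
    assert (gaps[gaps < 400] == 190).all()  # segment joins excluded


def test_spacing_law_of_large_numbers():
    cfg = small_config(chrom_length=3_000_000, centromere_intervals=[("chr1", 0, 3_000_000)],
                       satellite_arrays=[], seed=5)
    model = cc.plant_nucleosomes(cc.generate_genome(cfg))
    mids = np.sort(model.nucleosomes["mid"].to_numpy())
    gaps = np.diff(mids)
    gaps = gaps[gaps < 600]
    assert len(gaps) > 10_000
    assert abs(gaps.mean() - 190) < 1.0


def test_cenh3_midpoints_inside_centromeres(minimal_model):
    nuc = minimal_model.nucleosomes
    cen = minimal_model.features["centromeres"].iloc[0]
    cen_mids = nuc.loc[nuc["is_cenh3"], "mid"]
    assert ((cen_mids >= cen["start"]) & (cen_mids < cen["end"])).all()
    # one CENH3 nucleosome per monomer in arrays
    arr = minimal_model.features["arrays"].iloc[0]
    assert nuc["in_array"].sum() == arr["n_copies"]


# ------------------------------------------------------------- libraries
def test_empty_library_for_nonpositive_n(minimal_model):
    assert len(cc.simulate_library(minimal_model, "chip", 0)) == 0


def test_depletion_fold_zero_leaves_only_background():
    cfg = small_config(depleted_subdomains=[("chr1", 2_300_000, 2_400_000)],
                       depletion_fold=0.0, background_fraction=0.02)
    model = cc.plant_nucleosomes(cc.generate_genome(cfg))
    chip = cc.simulate_library(model, "chip", 100_000)
    mids = chip.midpoints
    in_dep = ((mids >= 2_300_000) & (mids < 2_400_000)).sum()
    # expected uniform background in the window: 2% of n * (100 kb / genome)
    expected_bg = 0.02 * 100_000 * 100_000 / sum(model.chrom_sizes.values())
    assert in_dep < 5 * expected_bg + 20


def test_infinite_bias_all_cuts_at_AT(minimal_model):
    model = minimal_model
    old = model.config.at_cut_bias
    model.config.at_cut_bias = np.inf
    try:
        naked = cc.simulate_library(model, "naked", 5_000, seed=9)
    finally:
        model.config.at_cut_bias = old
    starts = naked.df["start"].to_numpy()
    chroms = naked.df["chrom"].to_numpy()
    bases = np.array([model.sequence_str(c)[s] for c, s in zip(chroms[:1000], starts[:1000])])
    assert set(bases) <= {"A", "T"}


def test_enrichment_monotone_in_fold():
    means = []
    for fold in (5.0, 30.0):
        cfg = small_config(chip_enrichment_fold=fold, seed=2)
        model = cc.plant_nucleosomes(cc.generate_genome(cfg))
        chip = cc.simulate_library(model, "chip", 150_000)
        inp = cc.simulate_library(model, "input", 150_000)
        wt = cc.window_enrichment(chip, inp, model.chrom_sizes, window=10_000)
        cen = model.features["centromeres"].iloc[0]
        mid = (wt["start"] + wt["end"]) // 2
        in_cen = (wt["chrom"] == cen["chrom"]) & (mid >= cen["start"]) & (mid < cen["end"])
        means.append(wt.loc[in_cen, "enrichment"].mean())
    assert means[1] > means[0]


def test_fragment_length_model_modes(minimal_model):
    chip = cc.simulate_library(minimal_model, "chip", 150_000)
    dist = cc.length_modes(chip)
    assert dist.top_modes(1) == [147]
    under = cc.simulate_library(minimal_model, "chip", 150_000, underdigested=True)
    dist_u = cc.length_modes(under)
    assert dist_u.top_modes(1) == [158]  # 147 + 11-bp linker shift
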