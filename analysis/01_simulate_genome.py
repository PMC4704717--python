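"""Generate the maize-like synthetic genome and its sequencing libraries.

Builds seven chromosomes whose centromeres carry the published geometry —
sizes 1.82/1.00/0.93/1.88/1.88/1.26/1.65 Mb, two alternating CENH3-depleted
subdomains per centromere totalling 846 kb, one 256-copy satellite array
each, a 53% unique-sequence fraction, and 34 annotated genes (21 in depleted
subdomains, 11 of them active) — then simulates combined (0.2 U + 5 U) ChIP
and input libraries plus a naked-DNA MNase digest, and writes everything
under results/sim/.
"""

import sys
from pathlib import Path

import cenchrom as cc

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_CHIP = N_INPUT = 2_000_000
N_NAKED = 500_000


def main():
    outdir = RESULTS / "sim"
    cfg = cc.maize_preset(seed=SEED, n_fragments_chip=N_CHIP,
                          n_fragments_input=N_INPUT, n_fragments_naked=N_NAKED)
    model = cc.generate_genome(cfg)
    cc.plant_nucleosomes(model)
    paths = cc.write_truth(model, outdir)
    half = N_CHIP // 2
    chip = cc.FragmentSet.concat([
        cc.simulate_library(model, "chip", half),
        cc.simulate_library(model, "chip", N_CHIP - half, underdigested=True),
    ])
    inp = cc.FragmentSet.concat([
        cc.simulate_library(model, "input", half),
        cc.simulate_library(model, "input", N_INPUT - half, underdigested=True),
    ])
    naked = cc.simulate_library(model, "naked", N_NAKED)
    for name, fs in (("chip", chip), ("input", inp), ("naked", naked)):
        fs.to_bed(outdir / f"{name}.frags.bed")
    print(f"genome: {sum(model.chrom_sizes.values())/1e6:.1f} Mb over {len(model.chrom_sizes)} chromosomes")
    print(f"planted truth: {model.truth}")
    print(f"libraries: chip {len(chip):,}, input {len(inp):,}, naked {len(naked):,} fragments")
    print(f"outputs under {outdir}")


if __name__ == "__main__":
    main()
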