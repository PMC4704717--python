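"""Fragment-length distributions of the simulated libraries.

The fully digested (5 U-like) libraries peak at 147 bp — the nucleosome
core particle — with minor modes at 133 and 123 bp; the underdigested
(0.2 U-like) half of the library shifts up by the ~11-bp linker remnant to
~158 bp.  Writes the histogram and detected modes under results/.
"""

from pathlib import Path

import pandas as pd

from cenchrom.fragments import length_modes, load_fragments, quality_filter

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    fs = load_fragments(RESULTS / "sim" / "chip.frags.bed", library="chip")
    res = quality_filter(fs)
    print(f"quality filter kept {len(res.fragments):,}/{len(fs):,}; removals {res.removed}")
    dist = length_modes(res.fragments)
    pd.DataFrame({"length": dist.lengths, "fraction": dist.fractions}).to_csv(
        RESULTS / "fragment_lengths.tsv", sep="\t", index=False
    )
    print("top fragment-length modes (bp, by prominence):", dist.top_modes(4))


if __name__ == "__main__":
    main()
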