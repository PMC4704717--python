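"""End-to-end orchestration: simulate -> mappability -> domains ->
subdomains -> phasing -> satellite profile -> annotation -> expansion.

Every stage is a pure function of its inputs plus the run seed, so a rerun
with the same configuration reproduces the summary byte for byte.  Stage
outputs land in one directory; the machine-readable ``summary.json`` keys
mirror the generator's truth table so planted and recovered values can be
diffed directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, domains, mappability, nucpos, satellite, synth
from .fragments import FragmentSet, length_modes

log = logging.getLogger("cenchrom")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    preset: str = "minimal"  # "maize" | "minimal"
    seed: int = 0
    combine_libraries: bool = True
    n_fragments_chip: int | None = None
    n_fragments_input: int | None = None
    n_fragments_naked: int | None = None
    n_fragments_mark: int = 200_000
    island_params: domains.IslandParams = field(default_factory=domains.IslandParams)
    depleted_params: domains.DepletedParams = field(default_factory=domains.DepletedParams)
    generator_config: synth.GeneratorConfig | None = None
    input_files: dict = field(default_factory=dict)  # external inputs, validated at start

    def validate(self) -> None:
        for tag, p in self.input_files.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{tag} input file does not exist: {p}")
        self.island_params.__post_init__()
        self.depleted_params.__post_init__()


def _build_generator(cfg: RunConfig) -> synth.GeneratorConfig:
    if cfg.generator_config is not None:
        return cfg.generator_config
    if cfg.preset == "maize":
        g = synth.maize_preset(seed=cfg.seed)
    elif cfg.preset == "minimal":
        g = synth.minimal_preset(seed=cfg.seed)
    else:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    for attr in ("n_fragments_chip", "n_fragments_input", "n_fragments_naked"):
        v = getattr(cfg, attr)
        if v is not None:
            setattr(g, attr, v)
    return g


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the summary dict (also written to JSON)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "preset": cfg.preset}
    stage = "simulate"
    try:
        gcfg = _build_generator(cfg)
        model = synth.generate_genome(gcfg)
        synth.plant_nucleosomes(model)
        synth.write_truth(model, outdir / "sim")
        half = gcfg.n_fragments_chip // 2
        if cfg.combine_libraries:
            chip = FragmentSet.concat(
                [synth.simulate_library(model, "chip", half),
                 synth.simulate_library(model, "chip", gcfg.n_fragments_chip - half, underdigested=True)],
                library="chip",
            )
            inp = FragmentSet.concat(
                [synth.simulate_library(model, "input", half),
                 synth.simulate_library(model, "input", gcfg.n_fragments_input - half, underdigested=True)],
                library="input",
            )
        else:
            chip = synth.simulate_library(model, "chip", gcfg.n_fragments_chip)
            inp = synth.simulate_library(model, "input", gcfg.n_fragments_input)
        naked = synth.simulate_library(model, "naked", gcfg.n_fragments_naked)
        log.info("simulated %d chip, %d input, %d naked fragments", len(chip), len(inp), len(naked))
        summary["n_fragments"] = {"chip": len(chip), "input": len(inp), "naked": len(naked)}

        stage = "fragment_lengths"
        dist = length_modes(synth.simulate_library(model, "chip", min(len(chip), 100_000)))
        summary["fragment_length_modes"] = dist.top_modes(3)
        dist.lengths  # noqa: B018 - materialized below
        pd.DataFrame({"length": dist.lengths, "fraction": dist.fractions}).to_csv(
            outdir / "fragment_lengths.tsv", sep="\t", index=False
        )

        stage = "mappability"
        mask = mappability.unique_kmer_mask(model.sequences, k=150)
        window_table = mappability.mappable_windows(mask, model.chrom_sizes, window=cfg.depleted_params.window)
        window_table.to_csv(outdir / "windows_mappability.tsv", sep="\t", index=False)
        truth_cen = model.features["centromeres"]
        cen_map_pct = _centromeric_mappable_pct(window_table, truth_cen)
        summary["mappable_pct_centromere"] = round(cen_map_pct, 2)

        stage = "enrichment"
        enr = domains.window_enrichment(chip, inp, model.chrom_sizes, window=cfg.depleted_params.window)
        enr.to_csv(outdir / "window_enrichment.tsv", sep="\t", index=False)

        stage = "islands"
        islands = domains.call_islands(chip, inp, model.chrom_sizes, cfg.island_params)
        cens = domains.assemble_centromeres(islands, cfg.depleted_params)
        cens.to_csv(outdir / "centromeres_called.tsv", sep="\t", index=False)
        summary["n_centromeres_called"] = int(len(cens))
        summary["centromere_lengths_mb"] = [round(x / 1e6, 2) for x in cens.get("length", pd.Series(dtype=float))]

        stage = "depleted_subdomains"
        dep = domains.call_depleted(chip, inp, cens, window_table, cfg.depleted_params)
        dep.to_csv(outdir / "depleted_subdomains.tsv", sep="\t", index=False)
        tab = domains.summarize_subdomains(dep, cens, window_table)
        tab.to_csv(outdir / "subdomain_summary.tsv", sep="\t", index=False)
        total = tab.iloc[-1]
        summary["depleted_total_kb"] = round(float(total["depleted_kb"]), 1)
        summary["depleted_pct_mappable"] = round(float(total["depleted_pct"]), 2)

        stage = "phasing"
        summary["phasing"] = _phasing_stage(model, chip, outdir)

        stage = "satellite_profile"
        summary["satellite"] = _satellite_stage(model, chip, naked, outdir)

        stage = "annotation"
        summary["genes"], summary["marks"] = _annotation_stage(model, dep, cens, inp, cfg, outdir)

        stage = "expansion"
        summary["expansion"] = _expansion_stage(model, window_table, cfg)
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
        raise StageError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _centromeric_mappable_pct(window_table: pd.DataFrame, cens: pd.DataFrame) -> float:
    tot = mp = 0
    for cen in cens.itertuples(index=False):
        w = window_table.loc[
            (window_table["chrom"] == cen.chrom)
            & ((window_table["start"] + window_table["end"]) // 2 >= cen.start)
            & ((window_table["start"] + window_table["end"]) // 2 < cen.end)
        ]
        tot += len(w)
        mp += int(w["mappable"].sum())
    return 100.0 * mp / tot if tot else float("nan")


def _phasing_stage(model, chip, outdir) -> dict:
    out = {}
    arrays = model.features["arrays"]
    if len(arrays):
        a = arrays.iloc[0]
        ph = nucpos.phasogram(chip, (a["chrom"], int(a["start"]), int(a["end"])))
        est = nucpos.estimate_period(ph)
        ph.to_frame().to_csv(Path(outdir) / "phasogram_array.tsv", sep="\t", index=False)
        out["satellite_period"] = est.period
    cen = model.features["centromeres"].iloc[0]
    arr_b = arrays.loc[arrays["chrom"] == cen["chrom"]]
    # a non-satellite centromeric span: from the end of the last array to the
    # centromere end (or the whole centromere when there is no array)
    lo = int(arr_b["end"].max()) if len(arr_b) else int(cen["start"])
    region = (cen["chrom"], lo, int(cen["end"]))
    ph2 = nucpos.phasogram(chip, region)
    est2 = nucpos.estimate_period(ph2)
    ph2.to_frame().to_csv(Path(outdir) / "phasogram_noncentc.tsv", sep="\t", index=False)
    out["spacing_period"] = est2.period
    return out


def _satellite_stage(model, chip, naked, outdir) -> dict:
    ann = model.monomer_annotation()
    copies = [
        model.sequence_str(r.chrom)[r.start : r.end] for r in ann.head(500).itertuples(index=False)
    ]
    consensus = satellite.build_consensus(copies)
    prof_naked = satellite.project_cuts(naked, ann, consensus, source="naked")
    prof_chip = satellite.project_cuts(chip, ann, consensus, source="chip")
    prof_naked.to_frame().to_csv(Path(outdir) / "monomer_cuts_naked.tsv", sep="\t", index=False)
    prof_chip.to_frame().to_csv(Path(outdir) / "monomer_cuts_chip.tsv", sep="\t", index=False)
    at_naked = satellite.at_fraction(satellite.top_cut_sites(prof_naked), consensus)
    at_chip = satellite.at_fraction(satellite.top_cut_sites(prof_chip), consensus)
    return {
        "consensus_length": len(consensus),
        "at_pct_top_cuts_naked": round(at_naked, 1),
        "at_pct_top_cuts_chip": round(at_chip, 1),
    }


def _annotation_stage(model, dep, cens, inp, cfg, outdir):
    genes = model.features["genes"].loc[:, ["chrom", "start", "end", "name"]]
    classified = annotate.classify_genes(genes, dep, cens, model.expression)
    classified.to_csv(Path(outdir) / "genes_classified.tsv", sep="\t", index=False)
    gs = annotate.gene_summary(classified)
    gs.to_csv(Path(outdir) / "gene_summary.tsv", sep="\t", index=False)
    gene_out = {
        row["subdomain"]: {"active": int(row["active"]), "total": int(row["total"])}
        for _, row in gs.iterrows()
    }
    mark_islands = {}
    marks = sorted(model.features["mark_peaks"]["mark"].unique())
    for mark in marks:
        lib = synth.simulate_library(model, f"mark:{mark}", cfg.n_fragments_mark)
        mark_islands[mark] = domains.call_islands(lib, inp, model.chrom_sizes, cfg.island_params)
    ov = annotate.mark_overlap(mark_islands, dep, cens)
    ov.to_csv(Path(outdir) / "mark_overlap.tsv", sep="\t", index=False)
    mark_out = {
        r["mark"]: {"centromeric_kb": r["centromeric_kb"], "depleted_pct": None if pd.isna(r["depleted_pct"]) else round(r["depleted_pct"], 1)}
        for _, r in ov.iterrows()
    }
    # stash for the expansion stage
    model._mark_libraries = {m: synth.simulate_library(model, f"mark:{m}", cfg.n_fragments_mark) for m in marks}
    return gene_out, mark_out


def _expansion_stage(model, window_table, cfg) -> dict:
    exp = model.features["expansion"]
    if len(exp) == 0:
        return {}
    out = {}
    libs = getattr(model, "_mark_libraries", {})
    for mark, lib in libs.items():
        dens_e, dens_n = [], []
        for name, grp in exp.groupby("name"):
            e = grp.loc[grp["kind"] == "expanded"].iloc[0]
            nn = grp.loc[grp["kind"] == "nonexpanded"].iloc[0]
            for row, acc in ((e, dens_e), (nn, dens_n)):
                frac = _window_fracs(window_table, row["chrom"], int(row["start"]), int(row["end"]))
                acc.append(annotate.window_density(lib, (row["chrom"], int(row["start"]), int(row["end"])), 1000, frac))
        p, effect = annotate.expansion_bootstrap(
            np.concatenate(dens_e), np.concatenate(dens_n), B=10_000, seed=[cfg.seed, 23]
        )
        out[mark] = {"p": p, "effect": round(float(effect), 3)}
    return out


def _window_fracs(window_table, chrom, start, end, window=1000):
    """Per-1kb mappability fractions approximated from the 10-kb window table."""
    wt = window_table.loc[window_table["chrom"] == chrom].sort_values("start")
    starts = wt["start"].to_numpy()
    fracs = wt["mappable_frac"].to_numpy()
    pos = np.arange(start, end, window)
    idx = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(starts) - 1)
    return fracs[idx]
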