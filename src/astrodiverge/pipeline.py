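"""End-to-end orchestration: simulate -> quantify -> species/treatment DE ->
set statistics -> co-expression, with a JSON run manifest.

Stages communicate only through files in the package's TSV dialects, so any
stage can be re-run or replaced independently; the manifest records the
master seed, every stage parameter and a sha256 checksum of every output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import coexpr, quantify, species_de, treatment_de
from .io_formats import (ExpressionTable, read_expression, read_gene_lengths,
                         read_ortholog_table, write_expression, write_gene_lengths,
                         write_gene_set, write_ortholog_table)
from .synthetic_data import (TwoSpeciesSimConfig, gen_treatment_experiment,
                             gen_two_species_counts)

__all__ = ["run_pipeline", "report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"n_genes": 2000, "n_samples_per_group": 4},
    "species_de": {"adjust": "bh", "fdr": 0.05, "diff": 0.4,
                   "expressed_threshold": 1.0 / 3.0},
    "treat_de": {"fdr": 0.05, "fc": 1.5, "min_rpkm": 1.0},
    "coexpr": {"enabled": False, "power": 18.0, "min_module_size": 50,
               "cut_height": 0.995},
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(defaults: dict, override: dict | None) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in defaults.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run the synthetic end-to-end analysis; returns the manifest dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` per stage. Outputs and a
    ``manifest.json`` land in ``out_dir``. Re-running with an identical
    config and seed reproduces every file bit for bit.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"seed": seed, "parameters": cfg, "outputs": {}}

    def save_tsv(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        manifest["outputs"][name] = _sha256(path)

    def save_expr(expr: ExpressionTable, stem: str) -> None:
        write_expression(expr, out / f"{stem}.tsv", out / f"{stem}_meta.tsv")
        for suffix in ("", "_meta"):
            name = f"{stem}{suffix}.tsv"
            manifest["outputs"][name] = _sha256(out / name)

    # -- simulate -----------------------------------------------------------
    sim = TwoSpeciesSimConfig(seed=seed, **cfg["simulate"])
    acute_h, acute_m, orthologs, lengths, div_truth = gen_two_species_counts(sim)
    treat_h, treat_m, _, _, resp_truth = gen_treatment_experiment(sim)
    save_expr(acute_h, "acute_counts_human")
    save_expr(acute_m, "acute_counts_mouse")
    save_expr(treat_h, "treat_counts_human")
    save_expr(treat_m, "treat_counts_mouse")
    write_ortholog_table(orthologs, out / "orthologs.tsv")
    manifest["outputs"]["orthologs.tsv"] = _sha256(out / "orthologs.tsv")
    write_gene_lengths(lengths, out / "gene_lengths.tsv")
    manifest["outputs"]["gene_lengths.tsv"] = _sha256(out / "gene_lengths.tsv")
    save_tsv(div_truth.divergence.rename("label").to_frame(), "truth_divergence.tsv",
             index_label="gene_id")
    truth_resp = pd.DataFrame({"label": resp_truth.response,
                               "direction": resp_truth.response_direction})
    save_tsv(truth_resp, "truth_response.tsv", index_label="gene_id")

    # -- species divergence on percentile ranks -----------------------------
    sde = cfg["species_de"]
    rpkm_h = quantify.rpkm(acute_h, lengths)
    rpkm_m = quantify.rpkm(acute_m, lengths)
    perc_h = quantify.percentile_rank(rpkm_h)
    perc_m = quantify.percentile_rank(rpkm_m)
    expressed = species_de.filter_expressed(perc_h, perc_m, orthologs,
                                            threshold=sde["expressed_threshold"])
    diff_table = species_de.species_diff_test(perc_h, perc_m, expressed,
                                              adjust=sde["adjust"])
    human_higher, mouse_higher, _ = species_de.classify_divergent(
        diff_table, fdr_cut=sde["fdr"], diff_cut=sde["diff"])
    save_tsv(diff_table, "species_diff_table.tsv", index_label="human")
    write_gene_set(human_higher, out / "divergent_human_higher.txt")
    write_gene_set(mouse_higher, out / "divergent_mouse_higher.txt")
    for name in ("divergent_human_higher.txt", "divergent_mouse_higher.txt"):
        manifest["outputs"][name] = _sha256(out / name)

    # -- treatment DE per species + cross-species overlap -------------------
    tde = cfg["treat_de"]
    deg_sets = {}
    for species, expr in (("human", treat_h), ("mouse", treat_m)):
        controls = expr.samples_where(condition="control")
        treated = expr.samples_where(condition="treated")
        table = treatment_de.nb_two_group_test(expr, controls, treated, lengths=lengths)
        sets = treatment_de.deg_filter(table, fdr_cut=tde["fdr"], fc_cut=tde["fc"],
                                       rpkm_cut=tde["min_rpkm"])
        deg_sets[species] = sets
        save_tsv(table, f"deg_table_{species}.tsv", index_label="gene_id")
        write_gene_set(sets.up, out / f"deg_up_{species}.txt")
        write_gene_set(sets.down, out / f"deg_down_{species}.txt")
        for nm in (f"deg_up_{species}.txt", f"deg_down_{species}.txt"):
            manifest["outputs"][nm] = _sha256(out / nm)
    overlap = treatment_de.cross_species_deg_overlap(deg_sets["human"],
                                                     deg_sets["mouse"], orthologs)
    save_tsv(overlap, "deg_overlap.tsv", index_label="direction")

    # -- co-expression modules (optional; the heaviest stage) ---------------
    if cfg["coexpr"].get("enabled"):
        ncfg = coexpr.NetworkConfig(
            power=cfg["coexpr"]["power"],
            min_module_size=cfg["coexpr"]["min_module_size"],
            cut_height=cfg["coexpr"]["cut_height"])
        merged = coexpr.preprocess(treat_h, treat_m, orthologs, ncfg)
        corr, _ = coexpr.bicor(merged, c=ncfg.bicor_c)
        modules = coexpr.tom_modules(corr, merged, ncfg)
        save_tsv(modules.labels.rename("module").to_frame(), "modules.tsv",
                 index_label="gene_id")
        save_tsv(modules.eigengenes, "eigengenes.tsv", index_label="module")
        meta = pd.concat([treat_h.meta, treat_m.meta])
        traits = pd.DataFrame(index=merged.columns)
        for sp in ("human", "mouse"):
            traits[f"treated_{sp}"] = ((meta["condition"] == "treated")
                                       & (meta["species"] == sp)).astype(float)
        mt = coexpr.module_trait(modules.eigengenes, traits)
        save_tsv(mt, "module_trait.tsv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"incomplete run: {manifest_path} missing")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"astrodiverge run report — seed {manifest['seed']}", ""]

    diff = pd.read_csv(run / "species_diff_table.tsv", sep="\t", index_col=0)
    sde = manifest["parameters"]["species_de"]
    hh = (diff["p_adj"] < sde["fdr"]) & (diff["rank_diff"] > sde["diff"])
    mh = (diff["p_adj"] < sde["fdr"]) & (diff["rank_diff"] < -sde["diff"])
    lines += [
        f"orthologs tested for species divergence: {len(diff)}",
        f"  higher in human: {int(hh.sum())}",
        f"  higher in mouse: {int(mh.sum())}",
        "",
    ]
    for species in ("human", "mouse"):
        table = pd.read_csv(run / f"deg_table_{species}.tsv", sep="\t", index_col=0)
        n_up = sum(1 for _ in (run / f"deg_up_{species}.txt").read_text().splitlines() if _)
        n_dn = sum(1 for _ in (run / f"deg_down_{species}.txt").read_text().splitlines() if _)
        lines.append(f"{species} treatment DE: {len(table)} genes tested, "
                     f"{n_up} up, {n_dn} down")
    overlap = pd.read_csv(run / "deg_overlap.tsv", sep="\t", index_col=0)
    for direction, row in overlap.iterrows():
        lines.append(
            f"cross-species {direction} overlap: {int(row['n_overlap'])} of "
            f"{int(row['n_human'])} human genes ({row['pct_of_human']:.1f}%)")
    if (run / "module_trait.tsv").exists():
        mt = pd.read_csv(run / "module_trait.tsv", sep="\t")
        lines.append("")
        lines.append("module-trait correlations:")
        for _, row in mt.iterrows():
            lines.append(f"  module {int(row['module'])} ~ {row['trait']}: "
                         f"r={row['r']:+.3f} (p={row['p']:.2e})")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
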