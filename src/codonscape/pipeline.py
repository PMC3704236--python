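"""End-to-end orchestration: extract -> filter -> metrics -> preferred ->
cluster -> correlations -> Akashi -> structure -> tRNA, with per-stage
logging and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias_metrics import CodonCounts, background_composition, bias_profile, profiles_table
from .cug_clustering import (
    centered_heatmap_matrix,
    counts_matrix,
    fit_clusters,
    select_S,
)
from .conservation_tests import (
    build_akashi_tables,
    cmh_test,
    mh_common_odds_ratio,
    randomized_codon_set_reference,
    woolf_test,
)
from .preferred_codons import (
    evidence_table,
    family_frequency_matrix,
    identify_preferred_by_majority,
    identify_preferred_genomewide,
    spearman_correlation,
)
from .seq_models import apply_study_filters, extract_gene_records
from .structure_tests import BASE_FILTERS, structure_cmh
from .synthetic_data import read_alignment_fasta, read_fold_file
from .trna_correspondence import (
    pooled_codon_usage,
    trna_codon_correlation,
    trna_usage_frequencies,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds of one full analysis run."""

    genome: str
    gff: str
    expression: str
    outdir: str
    alignments_dir: str | None = None
    folds_dir: str | None = None
    trna: str | None = None
    flank_width: int = 1000
    min_expression: float = 200.0  # AU
    high_expression: float = 25000.0  # AU
    s_min: int = 1
    s_max: int = 8
    n_null_reps: int = 10
    n_random_sets: int = 1000
    n_restarts: int = 10
    seed: int = 0
    structure_alternative: str = "greater"
    conservation_alternative: str = "two_sided"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; write one TSV per report table.

    Returns the report bundle as a dict of DataFrames plus the manifest.
    Any stage failure leaves earlier outputs on disk and records the
    failure point in the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
        "failure": None,
    }
    bundle: dict = {"manifest": manifest}
    stage = "extract"
    try:
        expression = pd.read_csv(config.expression, sep="\t", index_col="gene_id")
        genes = extract_gene_records(
            config.genome, config.gff, config.flank_width, expression
        )
        manifest["stages"]["extract"] = {
            "n_genes": len(genes),
            "n_flagged": sum(1 for g in genes if g.qc_flags),
        }

        stage = "filter"
        counts_all = {g.gene_id: CodonCounts.from_cds(g.gene_id, g.cds) for g in genes}
        bg = background_composition(
            [g.flank_up for g in genes] + [g.flank_down for g in genes]
        )
        from .bias_metrics import nc_wright

        nc_all = {gid: nc_wright(c) for gid, c in counts_all.items()}
        retained = apply_study_filters(genes, expression, nc_all, config.min_expression)
        genes = [g for g in genes if g.gene_id in set(retained)]
        if not genes:
            raise RuntimeError(
                "no genes survived the expression/QC filters "
                f"(min_expression={config.min_expression} AU)"
            )
        manifest["stages"]["filter"] = {"n_retained": len(genes)}

        stage = "metrics"
        counts = [counts_all[g.gene_id] for g in genes]
        profiles = [bias_profile(g, bg, counts_all[g.gene_id]) for g in genes]
        prof = profiles_table(profiles)
        prof.to_csv(out / "profiles.tsv", sep="\t")
        bundle["profiles"] = prof
        manifest["stages"]["metrics"] = {"n_genes": len(prof)}

        stage = "preferred"
        freqs = family_frequency_matrix(counts)
        genome_pref = identify_preferred_genomewide(freqs, prof["Ncp"])
        evidence_table(genome_pref).to_csv(out / "preferred_genome.tsv", sep="\t", index=False)
        bundle["preferred_genome"] = genome_pref
        manifest["stages"]["preferred"] = {"n_assigned": len(genome_pref.choice)}

        stage = "cluster"
        X, ids = counts_matrix(counts)
        sel = select_S(
            X,
            range(config.s_min, config.s_max + 1),
            seed=config.seed,
            n_reps=config.n_null_reps,
            n_restarts=config.n_restarts,
            gene_ids=ids,
        )
        model = fit_clusters(
            X, sel.chosen_S, seed=config.seed, gene_ids=ids, n_restarts=config.n_restarts
        )
        sel.records.to_csv(out / "model_selection.tsv", sep="\t", index=False)
        assign = pd.DataFrame(
            {
                "gene_id": ids,
                "cluster": [model.assignments[g] for g in ids],
                "bg": [model.selfcons[g] for g in ids],
            }
        )
        assign.to_csv(out / "assignments.tsv", sep="\t", index=False)
        centered_heatmap_matrix(model).to_csv(out / "centered_usage.tsv", sep="\t")
        bundle["selection"], bundle["model"], bundle["assignments"] = sel, model, assign
        manifest["stages"]["cluster"] = {"chosen_S": sel.chosen_S, "B": model.B}

        stage = "correlations"
        expr_max = expression.loc[prof.index].max(axis=1)
        length = pd.Series(
            {g.gene_id: len(g.cds) // 3 for g in genes}, name="n_codons"
        ).loc[prof.index]
        targets = {
            "GC3": prof["GC3"],
            "GCcds": prof["GCcds"],
            "GCi": prof["GCi"],
            "GCf": prof["GCf"],
            "log10_max_expression": np.log10(expr_max.clip(lower=1e-6)),
            "n_codons": length,
        }
        groups = {"All": prof.index}
        for s in sorted(assign["cluster"].unique()):
            groups[f"CUG{s}"] = assign.loc[assign["cluster"] == s, "gene_id"]
        corr_rows = []
        for gname, idx in groups.items():
            for tname, series in targets.items():
                rho, p = spearman_correlation(
                    prof.loc[idx, "Ncp"].to_numpy(), series.loc[idx].to_numpy()
                )
                corr_rows.append({"group": gname, "variable": tname, "rho": rho, "p": p})
        corr = pd.DataFrame(corr_rows)
        corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
        bundle["correlations"] = corr
        manifest["stages"]["correlations"] = {"n_rows": len(corr)}

        cluster_of = dict(zip(assign["gene_id"], assign["cluster"]))
        counts_by_id = {c.gene_id: c for c in counts}
        group_pref = {}
        for gname, idx in groups.items():
            members = [counts_by_id[g] for g in idx]
            group_pref[gname] = identify_preferred_by_majority(members, scope=gname)

        if config.alignments_dir:
            stage = "akashi"
            alns = [
                read_alignment_fasta(p)
                for p in sorted(Path(config.alignments_dir).glob("*.afa"))
            ]
            alns = [a for a in alns if a.gene_id in cluster_of]
            rows = []
            for gname, idx in groups.items():
                idx_set = set(idx)
                sub = [a for a in alns if a.gene_id in idx_set]
                tables = build_akashi_tables(sub, group_pref[gname])
                if not tables:
                    continue
                chi2, p = cmh_test(tables, alternative=config.conservation_alternative)
                w_stat, w_df, w_p = (
                    woolf_test(tables) if len(tables) > 1 else (math.nan, 0, math.nan)
                )
                frac = randomized_codon_set_reference(
                    sub, group_pref[gname], n_sets=config.n_random_sets, seed=config.seed
                )
                rows.append(
                    {
                        "group": gname,
                        "n_genes": len(tables),
                        "MH_chi2": chi2,
                        "OR": mh_common_odds_ratio(tables),
                        "p": p,
                        "woolf_chi2": w_stat,
                        "woolf_df": w_df,
                        "woolf_p": w_p,
                        "p_better_codon_set": frac,
                    }
                )
            akashi = pd.DataFrame(rows)
            akashi.to_csv(out / "akashi.tsv", sep="\t", index=False)
            bundle["akashi"] = akashi
            manifest["stages"]["akashi"] = {"n_groups": len(akashi)}

        if config.folds_dir:
            stage = "structure"
            folds = {}
            seqs = {g.gene_id: g.cds for g in genes}
            for p in sorted(Path(config.folds_dir).glob("*.fold")):
                gid, _, ann = read_fold_file(p)
                if gid in seqs:
                    folds[gid] = ann
            rows = []
            for gname, idx in groups.items():
                sub = {g: seqs[g] for g in idx if g in folds}
                for bf in BASE_FILTERS:
                    res = structure_cmh(sub, folds, group_pref[gname], base_filter=bf)
                    rows.append({"group": gname, "base": bf, **res})
            structure = pd.DataFrame(rows)
            structure.to_csv(out / "structure.tsv", sep="\t", index=False)
            bundle["structure"] = structure
            manifest["stages"]["structure"] = {"n_rows": len(structure)}

        if config.trna:
            stage = "trna"
            trna_df = pd.read_csv(config.trna, sep="\t")
            rows = []
            for gname, idx in groups.items():
                usage = pooled_codon_usage([counts_by_id[g] for g in idx])
                tab = trna_usage_frequencies(trna_df, usage)
                for level in ("codon", "amino_acid"):
                    rho, p = trna_codon_correlation(tab, level=level)
                    rows.append({"group": gname, "level": level, "rho": rho, "p": p})
            trna_out = pd.DataFrame(rows)
            trna_out.to_csv(out / "trna_correlations.tsv", sep="\t", index=False)
            bundle["trna"] = trna_out
            manifest["stages"]["trna"] = {"n_rows": len(trna_out)}
    except Exception as exc:  # record failure point, keep partial outputs
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return bundle
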