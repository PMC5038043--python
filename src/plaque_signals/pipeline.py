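"""End-to-end orchestration.

A pipeline run loads (or synthesizes) a cohort, then executes the
analysis stages in order: cohort descriptives, rarefaction diversity
with stepwise covariate modeling, NB-GLM differential abundance,
percent-identity selection of phylotypes matching the
periodontitis-associated taxa, per-stratum compositional correlation
networks and Mantel-distance clustering of the strata.  Every stage
writes machine-readable files and the run ends with a JSON manifest of
output hashes, seeds and parameters.

One global seed deterministically spawns an independent substream per
stage (spawn key = fixed stage index), so toggling stages on or off
never changes another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_summary import cohort_summary
from .cooccurrence import (
    StratumKey,
    build_network,
    betweenness_ranking,
    cluster_strata,
    sparcc,
    permutation_pvalues,
    strong_edge_cutoff,
    stratify_counts,
)
from .differential_abundance import DesignSpec, run_differential_abundance
from .diversity import alpha_diversity, backward_stepwise_lm
from .io_core import (
    CountMatrix,
    SequenceSet,
    ValidationError,
    align_samples,
    read_count_table,
    read_fasta,
    read_metadata,
    write_count_table,
    write_fasta,
    write_metadata,
)
from .sequence_match import select_by_identity
from .synthetic import GeneratorConfig, generate_cohort, generate_sequences

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

# fixed spawn keys so per-stage streams are independent of stage toggles
_STAGE_IDS = {
    "synth": 0,
    "summarize": 1,
    "diversity": 2,
    "diffabund": 3,
    "select": 4,
    "network": 5,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage {stage!r} failed: {reason}")
        self.stage = stage
        self.reason = reason


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serializable)."""

    # either file inputs ...
    counts_path: str | None = None
    metadata_path: str | None = None
    fasta_path: str | None = None
    # ... or a synthetic block
    synthetic: dict | None = None
    stages: dict = field(
        default_factory=lambda: {
            "summarize": True,
            "diversity": True,
            "diffabund": True,
            "select": True,
            "network": True,
        }
    )
    # stage parameters, defaulting to the study's stated values
    rarefaction_depth: int = 5000
    rarefaction_iterations: int = 100
    rarefaction_mode: str = "without_replacement"
    fdr: float = 0.05
    sparcc_iterations: int = 20
    exclusion_threshold: float = 0.1
    n_permutations: int = 100
    edge_significance: float = 0.05
    identity_threshold: float = 98.5
    linkage: str = "complete"
    min_stratum_samples: int = 10
    seed: int = 0
    outdir: str = "plaque_signals_output"


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as handle:
        doc = yaml.safe_load(handle) or {}
    return PipelineConfig(**doc)


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGE_IDS[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=str)


def _load_inputs(
    config: PipelineConfig, outdir: Path, outputs: list[Path]
) -> tuple[CountMatrix, pd.DataFrame, SequenceSet | None]:
    if config.synthetic is not None:
        synth = dict(config.synthetic)
        gen_config = GeneratorConfig(
            n_samples=int(synth.get("n_samples", 500)),
            n_taxa=int(synth.get("n_taxa", 100)),
            libsize_mean=float(synth.get("libsize_mean", 13565.0)),
            libsize_sd=float(synth.get("libsize_sd", 6833.0)),
            dispersion=float(synth.get("dispersion", 0.3)),
        )
        seed = _stage_seed(config, "synth")
        counts, meta, truth = generate_cohort(gen_config, seed)
        seqs = generate_sequences(
            SequenceSet(
                [f"ref{i:04d}" for i in range(gen_config.n_taxa)],
                _random_reference_sequences(gen_config.n_taxa, seed),
            ),
            identity_targets=[100.0] * gen_config.n_taxa,
            seed=seed + 1,
        )
        seqs = SequenceSet(list(counts.taxon_ids), list(seqs.sequences))
        write_count_table(counts, outdir / "counts.tsv")
        write_metadata(meta, outdir / "metadata.tsv")
        write_fasta(seqs, outdir / "seqs.fasta")
        _write_json(
            {
                "effect_table": truth.effect_table.to_dict(orient="index"),
                "modules": [
                    {
                        "taxa": m.taxa,
                        "loading": m.loading,
                        "active_periodontitis": m.active_periodontitis,
                    }
                    for m in truth.modules
                ],
            },
            outdir / "truth.json",
        )
        outputs.extend(
            outdir / name
            for name in ("counts.tsv", "metadata.tsv", "seqs.fasta", "truth.json")
        )
        return counts, meta, seqs
    if not config.counts_path or not config.metadata_path:
        raise PipelineError("load", "need counts_path+metadata_path or a synthetic block")
    counts = read_count_table(config.counts_path)
    meta = read_metadata(config.metadata_path)
    counts, meta, _ = align_samples(counts, meta)
    seqs = read_fasta(config.fasta_path) if config.fasta_path else None
    return counts, meta, seqs


def _random_reference_sequences(n: int, seed: int, length: int = 370) -> list[str]:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return ["".join(rng.choice(bases, size=length)) for _ in range(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure raises ``PipelineError`` naming the stage;
    partial outputs written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    stage_info: dict[str, dict] = {}

    try:
        counts, meta, seqs = _load_inputs(config, outdir, outputs)
    except (ValidationError, OSError) as exc:
        raise PipelineError("load", str(exc)) from exc

    if config.stages.get("summarize", True):
        try:
            summary = cohort_summary(meta)
            strata = summary.pop("strata")
            strata.to_csv(outdir / "cohort_strata.tsv", sep="\t", index=False)
            _write_json(summary, outdir / "cohort_summary.json")
            outputs += [outdir / "cohort_strata.tsv", outdir / "cohort_summary.json"]
            stage_info["summarize"] = {"n": summary["n"]}
        except Exception as exc:
            raise PipelineError("summarize", str(exc)) from exc

    if config.stages.get("diversity", True):
        try:
            seed = _stage_seed(config, "diversity")
            estimates, excluded = alpha_diversity(
                counts,
                depth=config.rarefaction_depth,
                iterations=config.rarefaction_iterations,
                mode=config.rarefaction_mode,
                seed=seed,
            )
            estimates.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
            outputs.append(outdir / "diversity.tsv")
            model_info = {"excluded_samples": excluded}
            covar_cols = [
                c
                for c in ("bop", "periodontitis", "hiv", "age", "bmi", "education", "ses")
                if c in meta.columns
            ]
            merged = estimates.merge(meta, on="sample_id").dropna(
                subset=covar_cols
            )
            if len(merged) > len(covar_cols) + 2:
                covars = merged[covar_cols].astype(float)
                for response in ("richness", "shannon"):
                    result = backward_stepwise_lm(merged[response], covars)
                    model_info[response] = {
                        "retained_terms": result.retained_terms,
                        "aic_trace": result.aic_trace,
                        "coefficients": result.coefficients.to_dict(orient="index"),
                    }
            _write_json(model_info, outdir / "diversity_model.json")
            outputs.append(outdir / "diversity_model.json")
            stage_info["diversity"] = {
                "n_estimated": len(estimates),
                "n_excluded": len(excluded),
            }
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc

    diffabund = None
    if config.stages.get("diffabund", True):
        try:
            diffabund = run_differential_abundance(
                counts, meta, DesignSpec(), fdr=config.fdr, pseudo_reference=True
            )
            for term, table in diffabund["tables"].items():
                path = outdir / f"diffabund_{term}.tsv"
                table.to_csv(path, sep="\t")
                outputs.append(path)
            _write_json(diffabund["intersection"], outdir / "diffabund_intersection.json")
            outputs.append(outdir / "diffabund_intersection.json")
            stage_info["diffabund"] = {
                "n_skipped": len(diffabund["skipped"]),
                "n_samples_used": diffabund["n_samples_used"],
            }
        except Exception as exc:
            raise PipelineError("diffabund", str(exc)) from exc

    selected_taxa: list[str] | None = None
    if config.stages.get("select", True):
        try:
            perio_taxa = _periodontitis_taxa(diffabund)
            if seqs is None or not perio_taxa:
                selected_taxa = perio_taxa or None
                stage_info["select"] = {"n_selected": len(perio_taxa), "note": "no sequences or no hits"}
            else:
                refs = _subset_sequences(seqs, perio_taxa)
                selected_taxa, hits = select_by_identity(
                    seqs, refs, threshold=config.identity_threshold
                )
                frame = pd.DataFrame(
                    [
                        {
                            "query_id": h.query_id,
                            "reference_id": h.reference_id,
                            "identity": h.identity,
                            "selected": h.query_id in set(selected_taxa),
                        }
                        for h in hits.values()
                    ]
                )
                frame.to_csv(outdir / "selected_phylotypes.tsv", sep="\t", index=False)
                outputs.append(outdir / "selected_phylotypes.tsv")
                stage_info["select"] = {"n_selected": len(selected_taxa)}
        except Exception as exc:
            raise PipelineError("select", str(exc)) from exc

    if config.stages.get("network", True):
        try:
            seed = _stage_seed(config, "network")
            net_taxa = selected_taxa or _periodontitis_taxa(diffabund)
            if not net_taxa:
                # fall back to the most abundant taxa
                order = np.argsort(counts.counts.sum(axis=1))[::-1]
                net_taxa = [counts.taxon_ids[i] for i in order[:20]]
            net_taxa = [t for t in counts.taxon_ids if t in set(net_taxa)]
            sub = counts.select_taxa(net_taxa)
            strata_counts = stratify_counts(sub, meta, config.min_stratum_samples)
            corr_by_stratum: dict[StratumKey, np.ndarray] = {}
            rng = np.random.default_rng(seed)
            for key in sorted(strata_counts, key=lambda k: (k.periodontitis, k.bop)):
                stratum = strata_counts[key]
                keep = [
                    t
                    for t, row in zip(stratum.taxon_ids, stratum.counts)
                    if row.sum() > 0
                ]
                stratum = stratum.select_taxa(keep)
                if stratum.n_taxa < 3:
                    continue
                corr, _ = sparcc(
                    stratum,
                    inference_iters=config.sparcc_iterations,
                    exclusion_threshold=config.exclusion_threshold,
                    seed=int(rng.integers(2**31)),
                )
                pvals = permutation_pvalues(
                    stratum,
                    corr,
                    n_perm=config.n_permutations,
                    inference_iters=config.sparcc_iterations,
                    exclusion_threshold=config.exclusion_threshold,
                    seed=int(rng.integers(2**31)),
                )
                pd.DataFrame(corr, index=keep, columns=keep).to_csv(
                    outdir / f"corr_{key.label()}.tsv", sep="\t"
                )
                outputs.append(outdir / f"corr_{key.label()}.tsv")
                threshold = strong_edge_cutoff(corr)
                network = build_network(
                    keep, corr, pvals, threshold, config.edge_significance
                )
                edges = pd.DataFrame(
                    [
                        {"node_a": a, "node_b": b, "rho": rho}
                        for a, b, rho in network.edges
                    ]
                )
                edges.to_csv(outdir / f"edges_{key.label()}.tsv", sep="\t", index=False)
                outputs.append(outdir / f"edges_{key.label()}.tsv")
                nx.write_graphml(network.graph(), outdir / f"network_{key.label()}.graphml")
                outputs.append(outdir / f"network_{key.label()}.graphml")
                if len(network.node_ids) >= 3:
                    ranking = betweenness_ranking(network)
                    pd.DataFrame(ranking, columns=["node", "betweenness"]).to_csv(
                        outdir / f"betweenness_{key.label()}.tsv", sep="\t", index=False
                    )
                    outputs.append(outdir / f"betweenness_{key.label()}.tsv")
                # clustering uses the full (unthresholded) matrices on the
                # shared taxon set
                full = pd.DataFrame(corr, index=keep, columns=keep)
                corr_by_stratum[key] = full
            stage_info["network"] = {"n_strata": len(corr_by_stratum)}
            if len(corr_by_stratum) >= 2:
                shared = sorted(
                    set.intersection(*(set(f.index) for f in corr_by_stratum.values()))
                )
                if len(shared) >= 3:
                    mats = {
                        k: f.loc[shared, shared].to_numpy()
                        for k, f in corr_by_stratum.items()
                    }
                    _, labels, newick = cluster_strata(mats, method=config.linkage)
                    (outdir / "strata_dendrogram.nwk").write_text(newick + "\n")
                    outputs.append(outdir / "strata_dendrogram.nwk")
                    stage_info["network"]["dendrogram_labels"] = labels
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("network", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("outdir",)
        },
        "stages": stage_info,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _periodontitis_taxa(diffabund: dict | None) -> list[str]:
    if diffabund is None:
        return []
    table = diffabund["tables"].get("periodontitis")
    if table is None or len(table) == 0:
        return []
    hits = table[table["significant"] & (table["beta"] > 0)]
    if len(hits) >= 3:
        return list(hits.index)
    # fall back: the 20 most perio-leaning taxa by q among positive betas
    positive = table[table["beta"] > 0].sort_values("q")
    return list(positive.index[:20])


def _subset_sequences(seqs: SequenceSet, ids: list[str]) -> SequenceSet:
    index = {rid: s for rid, s in seqs}
    missing = [i for i in ids if i not in index]
    if missing:
        raise ValidationError(f"sequences missing for taxa: {missing[:5]}")
    return SequenceSet(list(ids), [index[i] for i in ids])
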