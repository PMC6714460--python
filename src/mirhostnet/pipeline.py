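"""Orchestration: run the full analysis for host/miRNA pairs from one config.

For each (host gene, miRNA) pair and each tissue the pipeline produces the
machine-readable analogues of the study's reporting surfaces: the
overlap/Venn counts with the hypergeometric depletion test, the
rank-comparison of target scores against all host-associated genes with
star codes, the centrality comparisons, the top-target table (gene, score,
fractional rank, validated flag), and the enrichment table; plus a
cross-tissue tissue-specificity summary per pair and a run-metadata file.
Reports are TSV/JSON, deterministic byte-for-byte under a fixed config and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment as enr
from . import filtering, integration, netstats
from . import io as io_formats
from .errors import ConfigurationError
from .types import (
    AssociationCriterion,
    FilteredTargetSet,
    TissueSpecificitySummary,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

_DEFAULTS = {
    "association_threshold": None,  # mandatory: no universal cutoff exists
    "association_direction": "above",
    "min_fr": filtering.DEFAULT_MIN_FR,
    "top_n": filtering.DEFAULT_TOP_N,
    "min_n": netstats.DEFAULT_MIN_N,
    "edge_weight_threshold": 0.5,
    "overlap_alternative": "depletion",
    "rank_test_alternative": "two-sided",
    "centrality_alternative": "greater",
    "enrichment_mode": "ora",
    "n_perm": 500,
    "self_target_mode": "warn",
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    if cfg["association_threshold"] is None:
        raise ConfigurationError(
            "association_threshold is mandatory (it defines 'interacting with "
            "the host gene' and is stamped into all outputs)"
        )
    if not cfg.get("pairs"):
        raise ConfigurationError("config lists no host/miRNA pairs")
    if cfg["enrichment_mode"] not in ("ora", "preranked"):
        raise ConfigurationError(f"unknown enrichment_mode {cfg['enrichment_mode']!r}")
    base = path.parent
    for pair in cfg["pairs"]:
        for key in ("host_gene", "mirna_id", "tissues", "predicted"):
            if key not in pair:
                raise ConfigurationError(f"pair is missing key {key!r}")
        for entry in pair["predicted"] + pair.get("validated", []):
            entry["path"] = str((base / entry["path"]).resolve())
            if not Path(entry["path"]).exists():
                raise ConfigurationError(f"missing input file {entry['path']}")
        for tissue, files in pair["tissues"].items():
            for k in list(files):
                files[k] = str((base / files[k]).resolve())
                if not Path(files[k]).exists():
                    raise ConfigurationError(f"missing input file {files[k]}")
        if "gene_sets" in pair:
            pair["gene_sets"] = str((base / pair["gene_sets"]).resolve())
            if not Path(pair["gene_sets"]).exists():
                raise ConfigurationError(f"missing input file {pair['gene_sets']}")
    return cfg


def _fmt(x: float) -> float:
    """Stable JSON-friendly rounding for report values."""
    return float(f"{x:.12g}")


def _rank_result_dict(res) -> dict:
    d = {
        "group_a_size": res.group_a_size,
        "group_b_size": res.group_b_size,
        "performed": res.performed,
    }
    if res.performed:
        d.update(
            statistic=_fmt(res.statistic),
            p_value=_fmt(res.p_value),
            stars=res.stars,
        )
    else:
        d["reason"] = res.reason_if_skipped
    return d


def tissue_specificity_summary(
    filtered_sets: dict[str, FilteredTargetSet]
) -> TissueSpecificitySummary:
    """How many tissues each filtered target appears in, plus pairwise overlap."""
    counts: dict[str, int] = {}
    for fts in filtered_sets.values():
        for g in fts.genes:
            counts[g] = counts.get(g, 0) + 1
    histogram: dict[int, int] = {}
    for c in counts.values():
        histogram[c] = histogram.get(c, 0) + 1
    tissues = sorted(filtered_sets)
    matrix = {}
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i:]:
            k = len(set(filtered_sets[t1].genes) & set(filtered_sets[t2].genes))
            matrix[(t1, t2)] = k
    return TissueSpecificitySummary(
        tissue_counts=counts, histogram=histogram, overlap_matrix=matrix
    )


def _write_filtered_targets(fts: FilteredTargetSet, path: Path) -> None:
    df = pd.DataFrame(
        [
            (m.gene, _fmt(m.netwas_score), _fmt(m.fractional_rank), m.validated)
            for m in fts.members
        ],
        columns=["gene", "netwas_score", "fractional_rank", "validated"],
    )
    df.to_csv(path, sep="\t", index=False)


def _write_enrichment(results, path: Path) -> None:
    rows = []
    for r in results:
        row = {
            "set_name": r.set_name,
            "description": r.description,
            "overlap": r.overlap_count,
            "set_size": r.set_size,
            "p_nominal": _fmt(r.p_nominal),
            "fdr_q": _fmt(r.fdr_q),
        }
        if r.es is not None:
            row["es"] = _fmt(r.es)
            row["nes"] = _fmt(r.nes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pair(cfg: dict, pair: dict, out_dir: Path) -> dict:
    """Run one host/miRNA pair across its tissues; returns the summary dict."""
    host = pair["host_gene"]
    mirna = pair["mirna_id"]
    criterion = AssociationCriterion(
        threshold=float(cfg["association_threshold"]),
        direction=cfg["association_direction"],
    )
    tables = [
        io_formats.read_target_table(e["path"], e["source"])
        for e in pair["predicted"]
    ]
    integrated = integration.integrate_predicted(tables, allow_multiple_mirnas=True)
    validated_tables = [
        io_formats.read_target_table(e["path"], e["source"])
        for e in pair.get("validated", [])
    ]
    validated = integration.integrate_validated(validated_tables)
    integrated = integration.annotate_validated(integrated, validated)
    self_hit, integrated = integration.check_host_self_target(
        integrated, host, mode=cfg["self_target_mode"]
    )

    prov_rows = [
        (g, ";".join(sorted(integrated.provenance[g])), g in integrated.validated)
        for g in sorted(integrated.targets)
    ]
    pd.DataFrame(prov_rows, columns=["gene", "sources", "validated"]).to_csv(
        out_dir / "integrated_targets.tsv", sep="\t", index=False
    )

    collection = (
        io_formats.read_gmt(pair["gene_sets"]) if "gene_sets" in pair else None
    )

    filtered_sets: dict[str, FilteredTargetSet] = {}
    tissue_reports: dict[str, dict] = {}
    for tissue in sorted(pair["tissues"]):
        files = pair["tissues"][tissue]
        tdir = out_dir / tissue
        tdir.mkdir(parents=True, exist_ok=True)
        vector = io_formats.read_association_table(files["association"], host, tissue)
        associated = filtering.host_associated_genes(vector, criterion)
        universe = vector.genes
        targets_in_universe = integrated.targets & universe
        filtered = filtering.filter_targets(integrated, associated)

        overlap = netstats.hypergeometric_overlap_test(
            len(universe),
            len(associated),
            len(targets_in_universe),
            len(filtered),
            alternative=cfg["overlap_alternative"],
        )

        report: dict = {
            "tissue": tissue,
            "counts": {
                "universe": overlap.universe_size,
                "associated": overlap.associated_count,
                "targets_in_universe": overlap.target_count,
                "overlap": overlap.overlap,
            },
            "overlap_test": {
                "alternative": overlap.alternative,
                "p_value": _fmt(overlap.p_value),
            },
        }

        if associated:
            franks = filtering.fractional_rank(vector, associated)
            rank_cmp = netstats.rank_score_comparison(
                [franks[g] for g in sorted(filtered)],
                [franks[g] for g in sorted(associated)],
                alternative=cfg["rank_test_alternative"],
                min_n=cfg["min_n"],
            )
            report["rank_comparison"] = _rank_result_dict(rank_cmp)
            fts = filtering.select_top_targets(
                filtered,
                franks,
                vector,
                host_gene=host,
                mirna_id=mirna,
                validated=integrated.validated,
                min_fr=cfg["min_fr"],
                top_n=cfg["top_n"],
            )
        else:
            report["rank_comparison"] = {"performed": False, "reason": "no test performed"}
            fts = FilteredTargetSet(
                host_gene=host, mirna_id=mirna, tissue=tissue, members=(), n_associated=0
            )
        filtered_sets[tissue] = fts
        _write_filtered_targets(fts, tdir / "filtered_targets.tsv")

        if "edges" in files:
            graph = io_formats.read_edge_list(
                files["edges"], tissue, nodes=universe | {host} | integrated.targets
            )
            profile = netstats.centrality_profile(
                graph, weight_threshold=cfg["edge_weight_threshold"]
            )
            deg_cmp, btw_cmp = netstats.compare_target_centrality(
                profile,
                targets_in_universe,
                filtered,
                alternative=cfg["centrality_alternative"],
                min_n=cfg["min_n"],
            )
            report["centrality"] = {
                "edge_weight_threshold": cfg["edge_weight_threshold"],
                "degree_comparison": _rank_result_dict(deg_cmp),
                "betweenness_comparison": _rank_result_dict(btw_cmp),
            }

        if collection is not None and len(fts):
            if cfg["enrichment_mode"] == "ora":
                results = enr.overrepresentation_test(
                    fts.genes, collection, universe
                )
            else:
                ranked = sorted(universe, key=lambda g: (-vector.scores[g], g))
                results = enr.preranked_significance(
                    ranked,
                    [vector.scores[g] for g in ranked],
                    collection,
                    n_perm=cfg["n_perm"],
                    seed=cfg["seed"],
                )
            _write_enrichment(results, tdir / "enrichment.tsv")
            report["enrichment"] = {
                "mode": cfg["enrichment_mode"],
                "n_sets": len(results),
                "best_set": results[0].set_name if results else None,
                "best_q": _fmt(results[0].fdr_q) if results else None,
            }
        tissue_reports[tissue] = report

    summary = tissue_specificity_summary(filtered_sets)
    spec_rows = [(g, c) for g, c in sorted(summary.tissue_counts.items())]
    pd.DataFrame(spec_rows, columns=["gene", "n_tissues"]).to_csv(
        out_dir / "tissue_specificity.tsv", sep="\t", index=False
    )

    return {
        "host_gene": host,
        "mirna_id": mirna,
        "host_self_target": self_hit,
        "n_integrated_targets": len(integrated),
        "n_validated": len(integrated.validated),
        "tissues": tissue_reports,
        "tissue_specificity": {
            "histogram": {str(k): v for k, v in sorted(summary.histogram.items())},
            "pairwise_overlap": {
                f"{a}|{b}": v for (a, b), v in sorted(summary.overlap_matrix.items())
            },
        },
    }


def run_full_analysis(config_path: str | Path, out_dir: str | Path) -> dict:
    """Execute every pair in the config; writes the full report bundle."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    (out / "config_used.yaml").write_text(cfg_text, encoding="utf-8")
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()

    pair_summaries = []
    for pair in cfg["pairs"]:
        pdir = out / f"{pair['host_gene']}_{pair['mirna_id']}"
        pdir.mkdir(parents=True, exist_ok=True)
        try:
            pair_summaries.append(run_pair(cfg, pair, pdir))
        except Exception as exc:
            (pdir / "INCOMPLETE").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(
                f"analysis of {pair['host_gene']}/{pair['mirna_id']} failed"
            ) from exc

    metadata = {
        "package_version": __version__,
        "config_sha256": cfg_hash,
        "seed": cfg["seed"],
        "association_threshold": cfg["association_threshold"],
        "association_direction": cfg["association_direction"],
        "min_fr": cfg["min_fr"],
        "top_n": cfg["top_n"],
        "min_n": cfg["min_n"],
        "edge_weight_threshold": cfg["edge_weight_threshold"],
        "enrichment_mode": cfg["enrichment_mode"],
        "pairs": pair_summaries,
    }
    with open(out / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return metadata
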