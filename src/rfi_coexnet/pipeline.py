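"""Pipeline orchestration: discovery and validation runs.

Discovery: feeding records -> phenotypes -> per-tissue expression filter
-> network/module detection -> module-trait correlation -> hub screening.
Validation: extreme-group selection (or explicit groups) -> gated
two-group comparison of the hub panel -> ADG correlation of the
significant genes.  Every stage writes its tabular artifact and the run
ends with a machine-readable JSON report reconciling the stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import phenotypes as ph
from .expression import ExpressionMatrix, FilterCriteria, filter_genes, write_expression_tsv
from .hubs import hub_edge_list, intramodular_connectivity, select_hubs
from .module_trait import module_trait_correlations
from .network import GREY, NetworkParams, detect_modules
from .validation import correlate_with_adg, two_group_compare

logger = logging.getLogger(__name__)

__all__ = ["DiscoveryConfig", "ValidationConfig", "run_discovery", "run_validation"]


@dataclass
class DiscoveryConfig:
    records: list[ph.FeedingRecord]
    tissues: dict[str, ExpressionMatrix]  # tissue name -> TPM matrix
    annotations: pd.Series  # gene_id -> description
    sample_individuals: dict[str, pd.Series] | None = None  # tissue -> sample->individual map
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    network_params: dict[str, NetworkParams] | None = None  # per tissue; default shared
    trait_name: str = "RFI"
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    top_n_hubs: int = 5
    out_dir: str | Path | None = None


@dataclass
class ValidationConfig:
    expr_high: pd.DataFrame  # genes x samples (high-efficiency group)
    expr_low: pd.DataFrame
    hub_genes: list[str]
    adg: pd.Series | None = None  # per individual, for growth correlation
    q_threshold: float = 0.1
    out_dir: str | Path | None = None


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / name, sep="\t", index=False)


def run_discovery(config: DiscoveryConfig) -> dict:
    """Run the full discovery pipeline; returns a results dict + report.

    The returned dict has per-tissue entries (modules, eigengenes,
    module-trait table, hubs) plus ``phenotypes``, ``rfi_fit`` and
    ``report``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    warnings: list[str] = []

    survivors = [r for r in config.records if r.survived]
    rows = ph.compute_phenotypes(survivors)
    fit = ph.fit_expected_dfi(rows)
    rows = ph.compute_rfi(rows, fit)
    pheno = ph.phenotypes_to_frame(rows)
    rfi_by_individual = pheno.set_index("individual_id")["RFI"]
    adg_by_individual = pheno.set_index("individual_id")["ADG"]
    _write(pheno, out_dir, "phenotypes.tsv")

    results: dict = {
        "phenotypes": pheno,
        "rfi_fit": fit,
        "tissues": {},
    }
    counts: dict = {}
    for tissue, expr in config.tissues.items():
        params = (config.network_params or {}).get(tissue, NetworkParams())
        filtered, filt_report = filter_genes(expr, config.filter_criteria)
        if filtered.n_genes == 0:
            warnings.append(f"{tissue}: no genes passed the expression filter")
            results["tissues"][tissue] = {"filter_report": filt_report}
            counts[tissue] = {"genes_in": expr.n_genes, "genes_filtered": 0}
            continue
        net = detect_modules(filtered, params)
        modules = net["modules"]

        # Trait per sample: map sample ids to individuals when a map is
        # given, else assume sample ids are individual ids.
        smap = (config.sample_individuals or {}).get(tissue)
        sample_ids = pd.Index(filtered.sample_ids)
        individuals = smap.reindex(sample_ids) if smap is not None else pd.Series(
            sample_ids, index=sample_ids
        )
        trait = pd.Series(
            rfi_by_individual.reindex(individuals).to_numpy(), index=sample_ids
        )
        if trait.isna().any():
            raise ValueError(
                f"{tissue}: no RFI phenotype for samples "
                f"{sample_ids[trait.isna()].tolist()[:5]}"
            )
        if net["eigengenes"].shape[1] > 0:
            mt = module_trait_correlations(
                net["eigengenes"], trait, config.trait_name,
                config.r_threshold, config.p_threshold,
            )
        else:
            mt = pd.DataFrame(columns=["module", "trait", "r", "p", "n", "selected"])
        selected = mt.loc[mt["selected"], "module"].tolist()
        if not selected:
            warnings.append(f"{tissue}: no trait-specific module")
        k_within = intramodular_connectivity(net["adjacency"], modules)
        hubs = (
            select_hubs(k_within, modules, config.annotations, selected, config.top_n_hubs)
            if selected
            else pd.DataFrame(
                columns=["gene_id", "module", "k_within", "annotation", "rank", "is_hub"]
            )
        )
        hub_genes = hubs.loc[hubs["is_hub"], "gene_id"].tolist()
        edges = hub_edge_list(net["adjacency"], hub_genes) if hub_genes else pd.DataFrame(
            columns=["gene_a", "gene_b", "weight"]
        )

        module_sizes = modules[modules != GREY].value_counts().to_dict()
        results["tissues"][tissue] = {
            "filter_report": filt_report,
            "power": net["power"],
            "scan": net["scan"],
            "modules": modules,
            "eigengenes": net["eigengenes"],
            "variance_explained": net["variance_explained"],
            "adjacency": net["adjacency"],
            "tom": net["tom"],
            "module_trait": mt,
            "selected_modules": selected,
            "k_within": k_within,
            "hubs": hubs,
            "hub_genes": hub_genes,
        }
        counts[tissue] = {
            "genes_in": expr.n_genes,
            "genes_filtered": filtered.n_genes,
            "modules_found": len(module_sizes),
            "genes_unassigned": int((modules == GREY).sum()),
            "modules_selected": len(selected),
            "hubs": len(hub_genes),
        }
        if out_dir is not None:
            tdir = out_dir / tissue
            tdir.mkdir(parents=True, exist_ok=True)
            modules.rename("module").to_frame().reset_index(names="gene_id").to_csv(
                tdir / "modules.tsv", sep="\t", index=False
            )
            net["eigengenes"].to_csv(tdir / "eigengenes.tsv", sep="\t")
            if net["scan"] is not None:
                net["scan"].table.to_csv(tdir / "soft_threshold_scan.tsv", sep="\t", index=False)
            mt.to_csv(tdir / "module_trait.tsv", sep="\t", index=False)
            hubs.to_csv(tdir / "hubs.tsv", sep="\t", index=False)
            edges.to_csv(tdir / "hub_edges.tsv", sep="\t", index=False)
            write_expression_tsv(filtered, tdir / "expression_filtered.tsv")

    report = {
        "stage": "discovery",
        "config_hash": _config_hash(
            {
                "filter": vars(config.filter_criteria),
                "trait": config.trait_name,
                "r_threshold": config.r_threshold,
                "p_threshold": config.p_threshold,
                "top_n_hubs": config.top_n_hubs,
            }
        ),
        "n_records": len(config.records),
        "n_survivors": len(survivors),
        "rfi_fit": {
            "b1": fit.b1, "b2": fit.b2, "b3": fit.b3,
            "rss": fit.rss, "n_obs": fit.n_obs, "converged": fit.converged,
        },
        "tissues": counts,
        "warnings": warnings,
        "elapsed_s": round(time.time() - t0, 3),
    }
    results["report"] = report
    results["adg_by_individual"] = adg_by_individual
    if out_dir is not None:
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    for w in warnings:
        logger.warning(w)
    return results


def run_validation(config: ValidationConfig) -> dict:
    """Validate a hub panel on an independent two-group cohort."""
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    present = [g for g in config.hub_genes if g in config.expr_high.index and g in config.expr_low.index]
    skipped = sorted(set(config.hub_genes) - set(present))
    if skipped:
        logger.warning("hub genes absent from the cohort, skipped: %s", skipped)
    comparison = two_group_compare(
        config.expr_high, config.expr_low, present, q_threshold=config.q_threshold
    )
    sig_genes = comparison.loc[comparison["significant"], "gene_id"].tolist()
    adg_cor = None
    if config.adg is not None and sig_genes:
        both = pd.concat([config.expr_high.loc[sig_genes], config.expr_low.loc[sig_genes]], axis=1)
        adg_cor = correlate_with_adg(both, config.adg)
    report = {
        "stage": "validation",
        "n_hub_genes": len(config.hub_genes),
        "n_tested": len(present),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "n_significant": len(sig_genes),
        "q_threshold": config.q_threshold,
        "elapsed_s": round(time.time() - t0, 3),
    }
    _write(comparison, out_dir, "validation.tsv")
    if adg_cor is not None:
        _write(adg_cor, out_dir, "adg_correlation.tsv")
    if out_dir is not None:
        (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    return {"comparison": comparison, "significant_genes": sig_genes, "adg_correlation": adg_cor, "report": report}
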