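"""End-to-end orchestration: preprocess → indexes → tests, from one config.

All randomness flows from a single root seed split into named substreams
(simulation, bootstrap, permutation), so e.g. the bootstrap band is stable
when the permutation test is toggled on or off, and per-parameter results
are independent of which other parameters are requested.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ExpressionMatrix,
    StageTimeline,
    TissuePanel,
    read_annotation,
    read_expression,
    read_timeline,
    read_tissue_panel,
)
from .preprocess import call_expressed, filter_low_mean, normalize_cpm, transform_expression
from .indexes import bootstrap_profile
from .analyses import (
    compare_param_by_group,
    connectivity_duplicability,
    permutation_test,
    pleiotropy_flags,
    pleiotropy_profile,
    retrogene_trend,
    tau,
)

__all__ = ["RunConfig", "run_pipeline", "component_seed"]

logger = logging.getLogger("devotei")

PARAMETERS = ("omega0", "phylostratum", "paralog_count", "connectivity")
DEFAULT_DIRECTIONS = {
    "omega0": "middle_lower",
    "phylostratum": "middle_lower",
    "paralog_count": "middle_lower",
    "connectivity": "middle_higher",
}
_SUBSTREAMS = {"simulation": 0, "bootstrap": 1, "permutation": 2}


def component_seed(root_seed: int, component: str, index: int = 0) -> int:
    """Derive a stable sub-seed for a named pipeline component."""
    ss = np.random.SeedSequence((root_seed, _SUBSTREAMS[component], index))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    expression: str
    scale: str
    timeline: str
    annotation: str
    out_dir: str
    tissue_panel: str | None = None
    transform: str = "log2"
    call_rule: str = "fpkm:1"
    filter_threshold: float | None = None
    parameters: list[str] = field(default_factory=lambda: list(PARAMETERS))
    directions: dict[str, str] = field(default_factory=dict)
    breadth_thresholds: list[float] = field(default_factory=lambda: [0.5])
    n_boot: int = 10_000
    n_perm: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)

    def direction_for(self, parameter: str) -> str:
        return self.directions.get(parameter, DEFAULT_DIRECTIONS.get(parameter, "middle_lower"))


def _parse_call_rule(rule: str) -> dict:
    kind, _, arg = rule.partition(":")
    if kind in ("fpkm", "threshold"):
        return {"rule": "threshold", "threshold": float(arg or 1.0)}
    if kind in ("rank", "rank_top"):
        return {"rule": "rank_top", "q": float(arg or 0.7)}
    raise ValueError(f"unknown call rule {rule!r}; use 'fpkm:<t>' or 'rank:<q>'")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured analysis and write all outputs to ``cfg.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = read_expression(cfg.expression, scale=cfg.scale)
    timeline = read_timeline(cfg.timeline)
    annotation = read_annotation(cfg.annotation)
    panel: TissuePanel | None = None
    if cfg.tissue_panel:
        panel = read_tissue_panel(cfg.tissue_panel)

    missing_stages = [s for s in timeline.stage_ids if s not in expr.stage_ids]
    if missing_stages:
        raise ValueError(f"timeline stages absent from expression matrix: {missing_stages}")
    expr = expr.with_data(expr.data[timeline.stage_ids])

    counts_log: dict[str, int] = {"input_genes": expr.shape[0]}
    logger.info("input: %d genes × %d stages", *expr.shape)

    if expr.scale == "raw_count":
        expr = normalize_cpm(expr)
        logger.info("normalized to counts-per-million")
    if cfg.filter_threshold is not None:
        expr = filter_low_mean(expr, cfg.filter_threshold)
        counts_log["genes_after_low_mean_filter"] = expr.shape[0]
        logger.info("low-mean filter (<%g): %d genes kept", cfg.filter_threshold, expr.shape[0])

    weights = transform_expression(expr, cfg.transform)

    manifest: dict = {
        "package": "devotei",
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest(),
        "gene_counts": counts_log,
        "results": {},
    }

    for j, parameter in enumerate(cfg.parameters):
        if parameter not in annotation.columns:
            raise ValueError(
                f"requested parameter {parameter!r} is not a column of the annotation file"
            )
        param = annotation[parameter].dropna()
        profile = bootstrap_profile(
            weights,
            param,
            n_boot=cfg.n_boot,
            seed=component_seed(cfg.seed, "bootstrap", j),
            parameter_name=parameter,
            transform_mode=cfg.transform,
        )
        profile.write(out / f"tei_{parameter}")
        direction = cfg.direction_for(parameter)
        test = permutation_test(
            weights,
            param,
            timeline,
            direction=direction,
            n_perm=cfg.n_perm,
            seed=component_seed(cfg.seed, "permutation", j),
        )
        (out / f"test_{parameter}.json").write_text(json.dumps(test.to_dict(), indent=2))
        counts_log[f"genes_with_{parameter}"] = profile.n_genes
        manifest["results"][parameter] = {
            "n_genes": profile.n_genes,
            "delta_observed": test.delta_observed,
            "p_normal": test.p_normal,
            "p_empirical": test.p_empirical,
            "direction": direction,
        }
        logger.info(
            "%s: n=%d Δe–m=%.4g p_normal=%.3g", parameter, profile.n_genes,
            test.delta_observed, test.p_normal,
        )

    # temporal pleiotropy on the linear-scale (pre-transform) matrix
    calls = call_expressed(expr, **_parse_call_rule(cfg.call_rule))
    for threshold in cfg.breadth_thresholds:
        flags = pleiotropy_flags(calls, breadth_threshold=threshold)
        result = pleiotropy_profile(calls, flags, breadth_threshold=threshold)
        tag = f"{int(round(threshold * 100))}"
        result.table.to_csv(out / f"pleiotropy_{tag}.tsv", sep="\t")
        summary = {
            "breadth_threshold": threshold,
            "chi2_statistic": result.chi2_statistic,
            "df": result.df,
            "p_value": result.p_value,
        }
        if "omega0" in annotation.columns and annotation["omega0"].notna().any():
            try:
                w_stat, w_p = compare_param_by_group(annotation["omega0"], flags)
                summary["omega0_wilcoxon"] = {"statistic": w_stat, "p_value": w_p}
            except ValueError:
                pass
        (out / f"pleiotropy_{tag}.json").write_text(json.dumps(summary, indent=2))
        manifest["results"][f"pleiotropy_{tag}"] = summary

    testis_specific: set[str] = set()
    if panel is not None:
        tau_table = tau(panel)
        tau_table.to_csv(out / "tau.tsv", sep="\t")
        testis_specific = set(tau_table.index[tau_table["is_testis_specific"]])
        manifest["results"]["tau"] = {
            "n_genes": len(tau_table),
            "n_testis_specific": len(testis_specific),
        }
        logger.info("tau: %d genes, %d testis-specific", len(tau_table), len(testis_specific))

    if "is_retrogene" in annotation.columns:
        retro = annotation["is_retrogene"].fillna(False).astype(bool)
        if retro.any():
            try:
                medians, rho, p = retrogene_trend(expr, retro, exclude=testis_specific or None)
                medians.rename("median_expression").to_csv(out / "retrogene_trend.tsv", sep="\t")
                manifest["results"]["retrogene_trend"] = {"rho": rho, "p_value": p}
            except ValueError as exc:
                manifest["results"]["retrogene_trend"] = {"error": str(exc)}

    if {"connectivity", "paralog_count"}.issubset(annotation.columns):
        try:
            rho, p, table, undefined = connectivity_duplicability(annotation)
            table.to_csv(out / "connectivity_duplicability.tsv", sep="\t")
            manifest["results"]["connectivity_duplicability"] = {
                "rho": None if undefined else rho,
                "p_value": None if undefined else p,
                "undefined": undefined,
            }
        except ValueError as exc:
            manifest["results"]["connectivity_duplicability"] = {"error": str(exc)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
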