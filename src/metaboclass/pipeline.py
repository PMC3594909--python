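"""End-to-end orchestration: simulate/load -> evaluate -> rank -> report.

A :class:`RunConfig` fully determines a run: the input table (CSV path or
simulation parameters), the analysis case, the classifier configurations,
the evaluation schedule and the master seed. Every stochastic stage draws
from a child seed derived from the master seed and the stage name, so
editing one stage's schedule never perturbs another stage's stream, and a
re-run with the same config and seed is byte-identical.

All pass/fail surfaces are the CSV/JSON artifacts; plots are optional
conveniences.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifiers import METHODS, ClassifierSpec, RankList, rank_variables
from .errors import StageError, ValidationError
from .preprocess import PreprocessConfig
from .ranking import pearson_consistency, select_biomarkers, ttest_rank
from .simulate import SimConfig, assemble_case, generate_dataset, generate_three_group
from .tables import FeatureTable, read_feature_table, write_feature_table
from .validation import (
    cv_scores,
    holdout_cv,
    kfold_cv,
    permutation_diagnostic,
    roc_auc,
    variable_elimination,
)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "DEFAULT_SCHEMES"]

#: The five cross-validation schemes of the default evaluation schedule.
DEFAULT_SCHEMES: tuple[str, ...] = (
    "kfold:7",
    "kfold:10",
    "holdout:0.1",
    "holdout:0.15",
    "holdout:0.33",
)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable content hash, < 2**31)."""
    digest = hashlib.sha256(f"{int(master)}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def parse_scheme(scheme: str) -> tuple[str, float]:
    """Parse ``"kfold:7"`` or ``"holdout:0.33"`` into (kind, parameter)."""
    try:
        kind, raw = scheme.split(":")
        value = float(raw)
    except ValueError as exc:
        raise ValidationError(f"malformed CV scheme {scheme!r}") from exc
    if kind == "kfold":
        if value < 2 or value != int(value):
            raise ValidationError(f"k-fold scheme needs an integer k >= 2, got {raw}")
        return "kfold", value
    if kind == "holdout":
        if not 0 < value < 1:
            raise ValidationError(f"holdout fraction must lie in (0, 1), got {raw}")
        return "holdout", value
    raise ValidationError(f"unknown CV scheme kind {kind!r}")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    table_path: str | None = None
    sim: SimConfig | None = None
    three_group: bool = False
    case: tuple[str, str] | None = None
    methods: tuple[str, ...] = METHODS
    schemes: tuple[str, ...] = DEFAULT_SCHEMES
    holdout_repeats: int = 100
    n_perm: int = 100
    elimination: bool = True
    elimination_k: int = 7
    thresholds: tuple[float, float, float] = (0.05, 1.0, 50.0)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier_options: dict = field(default_factory=dict)
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.table_path is None and self.sim is None and not self.three_group:
            raise ValidationError("config needs a table_path or simulation parameters")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValidationError(f"unknown method(s) {sorted(unknown)}")
        for s in self.schemes:
            parse_scheme(s)
        if self.holdout_repeats < 1:
            raise ValidationError(f"holdout_repeats must be >= 1, got {self.holdout_repeats}")
        if self.n_perm < 0:
            raise ValidationError(f"n_perm must be >= 0, got {self.n_perm}")

    def classifier_spec(self, method: str) -> ClassifierSpec:
        opts = dict(self.classifier_options.get(method, {}))
        return ClassifierSpec(
            method=method, seed=stage_seed(self.seed, f"fit/{method}"), **opts
        )

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["preprocess"] = dataclasses.asdict(self.preprocess)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        for key in ("methods", "schemes", "thresholds"):
            d[key] = list(d[key])
        if d["case"] is not None:
            d["case"] = list(d["case"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None and not isinstance(d["sim"], SimConfig):
            d["sim"] = SimConfig(**d["sim"])
        if d.get("preprocess") is not None and not isinstance(d["preprocess"], PreprocessConfig):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        for key in ("methods", "schemes", "thresholds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("case") is not None:
            d["case"] = tuple(d["case"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _load_table(config: RunConfig) -> FeatureTable:
    if config.table_path is not None:
        table = read_feature_table(config.table_path)
    elif config.three_group:
        table = generate_three_group(config.sim or SimConfig())
    else:
        table = generate_dataset(config.sim or SimConfig())
    if config.case is not None:
        table = assemble_case(table, config.case)
    elif len(set(table.groups)) != 2:
        raise ValidationError(
            f"table has groups {sorted(set(table.groups))}; give a two-group "
            "case definition to analyse it"
        )
    return table


def _evaluate_method(config: RunConfig, table: FeatureTable, method: str) -> dict:
    spec = config.classifier_spec(method)
    out: dict = {"cv": {}}
    for scheme in config.schemes:
        kind, value = parse_scheme(scheme)
        seed = stage_seed(config.seed, f"cv/{method}/{scheme}")
        if kind == "kfold":
            res = kfold_cv(spec, table, int(value), seed=seed, preprocess=config.preprocess)
        else:
            res = holdout_cv(
                spec, table, value, n_repeats=config.holdout_repeats,
                seed=seed, preprocess=config.preprocess,
            )
        out["cv"][scheme] = res
    if config.n_perm >= 2:
        out["permutation"] = permutation_diagnostic(
            spec, table, n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"perm/{method}"),
            preprocess=config.preprocess,
        )
    scores = cv_scores(
        spec, table, k=7, seed=stage_seed(config.seed, f"roc/{method}"),
        preprocess=config.preprocess,
    )
    out["roc"] = roc_auc(scores, table.labels)
    if config.elimination:
        out["elimination"] = variable_elimination(
            spec, table, k=config.elimination_k,
            seed=stage_seed(config.seed, f"elim/{method}"),
            preprocess=config.preprocess,
        )
    return out


def _rank_stage(config: RunConfig, table: FeatureTable) -> dict:
    from .preprocess import preprocess_table

    pretreated = preprocess_table(table, config.preprocess)
    lists: dict[str, RankList] = {"tRank": ttest_rank(pretreated)}
    label_map = {"pls": "PLSRank", "rf": "RFRank", "svm": "SVMRank", "lda": "LDARank"}
    for method in config.methods:
        lists[label_map[method]] = rank_variables(config.classifier_spec(method), pretreated)
    out: dict = {"rank_lists": lists}
    out["consistency_all"] = pearson_consistency(lists, level="all_variables")
    if table.identified_mask is not None and int(table.identified_mask.sum()) >= 3:
        ids = [str(v) for v, m in zip(table.variable_ids, table.identified_mask) if m]
        out["consistency_identified"] = pearson_consistency(
            lists, subset=ids, level="identified_metabolites"
        )
    p_cut, vip_cut, gini_cut = config.thresholds
    out["biomarkers"] = select_biomarkers(
        pretreated, p_cut=p_cut, vip_cut=vip_cut, gini_cut=gini_cut,
        pls_spec=config.classifier_spec("pls"), rf_spec=config.classifier_spec("rf"),
    )
    return out


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def _write_stage(outdir: Path, manifest: dict, name: str, path: Path) -> None:
    manifest["artifacts"][name] = str(path.relative_to(outdir))


def _float(x) -> float:
    return float(np.round(float(x), 12))  # stable text representation


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full benchmark and (optionally) write the report bundle.

    Returns a dictionary with the analysed table, per-method evaluation
    results, rankings/consistency/biomarkers and the artifact manifest.
    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written by earlier stages are preserved.
    """
    out: Path | None = Path(outdir) if outdir is not None else None
    manifest: dict = {"seed": config.seed, "artifacts": {}}
    bundle: dict = {"config": config, "manifest": manifest}
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    def _stage(name, fn):
        try:
            return fn()
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    table = _stage("input", lambda: _load_table(config))
    bundle["table"] = table
    if out is not None:
        _write_stage(out, manifest, "table", write_feature_table(table, out / "table.csv"))

    results: dict[str, dict] = {}
    for method in config.methods:
        results[method] = _stage(
            f"evaluate/{method}", lambda m=method: _evaluate_method(config, table, m)
        )
        if out is not None:
            _write_method_artifacts(out, manifest, method, results[method])
    bundle["results"] = results

    ranks = _stage("rank", lambda: _rank_stage(config, table))
    bundle.update(ranks)
    if out is not None:
        _write_rank_artifacts(out, manifest, ranks)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        if config.make_plots:
            from . import plots

            _stage("plots", lambda: plots.write_all(bundle, out / "plots"))
    return bundle


def _write_method_artifacts(out: Path, manifest: dict, method: str, res: dict) -> None:
    rows = []
    for scheme, cv in res["cv"].items():
        for i, (err, size) in enumerate(zip(cv.errors, cv.sizes)):
            rows.append(
                {"method": method, "scheme": scheme, "repeat": i, "error": _float(err),
                 "holdout_size": int(size)}
            )
    path = out / f"cv_{method}.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_stage(out, manifest, f"cv/{method}", path)

    summary = {
        scheme: {"mean_error": _float(cv.mean_error), "sd_error": _float(cv.sd_error),
                 "n_repeats": cv.n_repeats, **{k: _float(v) for k, v in cv.boxplot_stats().items()}}
        for scheme, cv in res["cv"].items()
    }
    summary["roc_auc"] = _float(res["roc"].auc)
    if "permutation" in res:
        diag = res["permutation"]
        summary["permutation"] = {
            "r2_actual": _float(diag.r2_actual),
            "q2_actual": _float(diag.q2_actual),
            "r2_intercept": _float(diag.r2_intercept),
            "q2_intercept": _float(diag.q2_intercept),
            "criterion1": diag.criterion1,
            "criterion2": diag.criterion2,
            "valid": diag.valid,
        }
        perm_path = out / f"permutation_{method}.csv"
        pd.DataFrame(
            {
                "correlation": np.round(diag.perm_correlations, 12),
                "r2": np.round(diag.perm_r2, 12),
                "q2": np.round(diag.perm_q2, 12),
            }
        ).to_csv(perm_path, index=False)
        _write_stage(out, manifest, f"permutation/{method}", perm_path)
    spath = out / f"summary_{method}.json"
    spath.write_text(json.dumps(summary, indent=1, sort_keys=True))
    _write_stage(out, manifest, f"summary/{method}", spath)

    rpath = out / f"roc_{method}.csv"
    pd.DataFrame(res["roc"].points, columns=["fpr", "tpr"]).to_csv(rpath, index=False)
    _write_stage(out, manifest, f"roc/{method}", rpath)

    if "elimination" in res:
        epath = out / f"elimination_{method}.csv"
        curve = res["elimination"]
        pd.DataFrame(
            {
                "n_variables": curve.counts,
                "error": np.round(curve.errors, 12),
                "removed": list(curve.elimination_order),
            }
        ).to_csv(epath, index=False)
        _write_stage(out, manifest, f"elimination/{method}", epath)


def _write_rank_artifacts(out: Path, manifest: dict, ranks: dict) -> None:
    rows = []
    for name, rl in ranks["rank_lists"].items():
        for pos, (vid, score) in enumerate(zip(rl.variable_ids, rl.scores), start=1):
            rows.append({"method": name, "rank": pos, "variable": vid, "score": _float(score)})
    path = out / "rank_lists.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_stage(out, manifest, "rank_lists", path)

    for key, fname in (
        ("consistency_all", "consistency_all.csv"),
        ("consistency_identified", "consistency_identified.csv"),
    ):
        if key in ranks:
            cpath = out / fname
            ranks[key].to_dataframe().round(12).to_csv(cpath)
            _write_stage(out, manifest, key, cpath)

    bpath = out / "biomarkers.json"
    bpath.write_text(json.dumps(ranks["biomarkers"].to_dict(), indent=1, sort_keys=True))
    _write_stage(out, manifest, "biomarkers", bpath)
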