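"""End-to-end pipeline: score → cohort → describe → associate → random forest.

``run_all`` chains every stage on a participant table (read from disk or
freshly simulated), writes each artifact under the output directory, and
records a manifest with the seed fan-out, input hash and package versions so
reruns are auditable.  Any stage failure writes a ``FAILED`` marker naming
the stage and re-raises; artifacts produced before the failure are kept.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import ORTable, fit_logistic_model
from .cohort import CohortDataset, build_cohort, intake_frame
from .compare import GroupComparisonResult, compare_continuous, summarize_categorical, tertile_table
from .reference import ReferenceTable, load_reference_table
from .rf import RFResult, default_feature_frame, fit_rf_cv, rank_dietary_features
from .scoring import DEFAULT_MIN_PARAMETERS, score_frame
from .simulate import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_all", "comparison_to_dict", "or_table_to_dict",
           "rf_result_to_dict", "describe_groups", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Switches for one end-to-end run."""

    output_dir: str = "dii_run"
    reference: str | None = None
    min_parameters: int = DEFAULT_MIN_PARAMETERS
    seed: int = 17
    models: tuple[int, ...] = (1, 2, 3)
    rf_trees: int = 200
    rf_folds: int = 10
    rf_subgroups: tuple[str, ...] = ("all", "male", "female")
    run_rf: bool = True
    run_tertiles: bool = True
    n_simulate: int | None = None  # simulate instead of reading when set

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["rf_subgroups"] = list(self.rf_subgroups)
        return d


def comparison_to_dict(res: GroupComparisonResult) -> dict:
    out = {
        "variable": res.variable,
        "method": res.method,
        "statistic": res.statistic,
        "p_value": res.p_value,
        "significant": res.significant,
        "groups": {g: dict(v) for g, v in res.groups.items()},
        "denominators": dict(res.denominators),
    }
    if res.homogeneity is not None:
        out["levene"] = {"statistic": res.homogeneity[0], "p": res.homogeneity[1]}
    if res.posthoc is not None:
        name, pairs = res.posthoc
        out["posthoc"] = {"method": name,
                         "pairwise_p": {f"{a} vs {b}": p for (a, b), p in pairs.items()}}
    return out


def or_table_to_dict(table: ORTable) -> dict:
    return {
        "model_id": table.model_id,
        "n_used": table.n_used,
        "covariates": list(table.covariate_spec),
        "rows": [
            {"term": r.term, "level": r.level, "OR": r.or_, "ci_low": r.ci_low,
             "ci_high": r.ci_high, "p_value": r.p_value, "is_reference": r.is_reference}
            for r in table.rows
        ],
    }


def rf_result_to_dict(res: RFResult, top_k: int = 10) -> dict:
    return {
        "subgroup": res.subgroup,
        "auc": res.auc,
        "per_fold_auc": res.per_fold_auc,
        "n_trees": res.n_trees,
        "folds": res.folds,
        "seed": res.seed,
        "n_participants": int(len(res.cv_predictions)),
        "top_dietary_features": rank_dietary_features(res, top_k=top_k)
        .to_dict(orient="records"),
        "feature_importances": res.feature_importances.to_dict(orient="records"),
    }


def describe_groups(records: pd.DataFrame, group_col: str = "group") -> dict:
    """Case/control descriptive table over the default variable set."""
    results: dict[str, GroupComparisonResult] = {}
    continuous = [c for c in ["age", "bmi", "waist_cm", "dii_total"]
                  if c in records.columns]
    continuous += [c for c in records.columns if c.startswith("lab_")]
    categorical = [c for c in ["sex", "race", "education", "income_band", "smoking",
                               "hypertension", "diabetes", "prediabetes",
                               "coronary_artery_disease", "angina", "heart_attack",
                               "stroke"] if c in records.columns]
    for var in continuous:
        results[var] = compare_continuous(records, var, group_col=group_col)
    for var in categorical:
        results[var] = summarize_categorical(records, var, group_col=group_col)
    return {v: comparison_to_dict(r) for v, r in results.items()}


def _hash_frame(frame: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(frame, index=True).to_numpy().tobytes())
    h.update(",".join(map(str, frame.columns)).encode())
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    participants: pd.DataFrame | None = None,
    scenario: SyntheticConfig | None = None,
) -> dict:
    """Execute the full analysis chain and write all artifacts.

    Provide either a participant table or a synthetic scenario (with
    ``config.n_simulate`` set).  Returns the in-memory report bundle.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1))
                   for s in ("simulate", "rf")}
    bundle: dict = {}
    current_stage = "setup"

    def _fail(err: BaseException):
        (out_dir / "FAILED").write_text(f"stage: {current_stage}\nerror: {err}\n")
        raise StageError(current_stage, err) from err

    try:
        current_stage = "input"
        reference = load_reference_table(config.reference)
        if participants is None:
            if config.n_simulate is None:
                raise ValueError("provide a participant table or set n_simulate")
            scenario = scenario or SyntheticConfig()
            scenario.n_participants = config.n_simulate
            scenario.seed = stage_seeds["simulate"]
            participants, truth = generate_cohort(scenario)
            bundle["ground_truth"] = {
                k: v for k, v in truth.items() if not isinstance(v, pd.Series)
            }
        input_hash = _hash_frame(participants)

        current_stage = "score"
        diet = intake_frame(participants)
        if diet.shape[1] == 0:
            raise ValueError("no diet_* columns present; cannot compute DII scores")
        scored = score_frame(diet, reference, min_parameters=config.min_parameters,
                             contributions=True)
        scores_out = pd.concat(
            [participants[["participant_id"]], scored], axis=1
        )
        scores_out.to_csv(out_dir / "scores.csv", index=False)
        bundle["scores"] = scored

        current_stage = "cohort"
        cohort: CohortDataset = build_cohort(
            participants, reference=reference, min_parameters=config.min_parameters,
            scorable=scored["scorable"],
        )
        records = cohort.records.copy()
        records["dii_total"] = scored["dii_total"].reindex(records.index)
        records.to_csv(out_dir / "cohort.csv", index=False)
        with open(out_dir / "flow.json", "w") as fh:
            json.dump(cohort.flow.to_dict(), fh, indent=2)
        bundle["cohort"] = cohort
        bundle["flow"] = cohort.flow.to_dict()

        current_stage = "describe"
        table1 = describe_groups(records)
        with open(out_dir / "table1.json", "w") as fh:
            json.dump(table1, fh, indent=2)
        bundle["table1"] = table1
        if config.run_tertiles and cohort.flow.n_hf >= 3:
            tert, table2 = tertile_table(records, records["dii_total"])
            bundle["tertiles"] = tert
            table2_dict = {v: comparison_to_dict(r) for v, r in table2.items()}
            table2_dict["_tertile_meta"] = {
                "boundaries": list(tert.boundaries),
                "counts": tert.counts,
                "ranges": {k: list(v) for k, v in tert.ranges.items()},
            }
            with open(out_dir / "table2.json", "w") as fh:
                json.dump(table2_dict, fh, indent=2)
            bundle["table2"] = table2_dict

        current_stage = "associate"
        or_tables = {}
        for model_id in config.models:
            table = fit_logistic_model(records, records["dii_total"], model_id)
            or_tables[model_id] = table
            table.to_frame().to_csv(out_dir / f"or_model{model_id}.csv", index=False)
            with open(out_dir / f"or_model{model_id}.json", "w") as fh:
                json.dump(or_table_to_dict(table), fh, indent=2)
        bundle["or_tables"] = or_tables

        if config.run_rf:
            current_stage = "rf"
            rf_results = {}
            labels_all = (records["group"] == "HF").astype(int)
            for subgroup in config.rf_subgroups:
                sub = records if subgroup == "all" else records[records["sex"] == subgroup]
                feats = default_feature_frame(sub)
                if subgroup != "all":
                    feats = feats.drop(columns=["sex_female"], errors="ignore")
                res = fit_rf_cv(
                    feats, labels_all.reindex(sub.index), subgroup=subgroup,
                    n_trees=config.rf_trees, folds=config.rf_folds,
                    seed=stage_seeds["rf"],
                )
                rf_results[subgroup] = res
                with open(out_dir / f"rf_{subgroup}.json", "w") as fh:
                    json.dump(rf_result_to_dict(res), fh, indent=2)
                pd.DataFrame(res.roc_points, columns=["fpr", "tpr"]).to_csv(
                    out_dir / f"roc_{subgroup}.csv", index=False
                )
            bundle["rf"] = rf_results

        current_stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": stage_seeds,
            "input_hash": input_hash,
            "reference_hash": _hash_frame(reference.to_frame()),
            "config": config.to_dict(),
            "flow": bundle["flow"],
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        bundle["manifest"] = manifest
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - stage attribution contract
        _fail(err)
    return bundle
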