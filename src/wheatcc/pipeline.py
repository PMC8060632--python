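"""End-to-end orchestration: images/tables → fits → comparisons → NNI.

The pipeline either consumes real inputs (an image directory plus a
plot-metadata CSV, joined with a destructive-sampling CSV) or generates a
synthetic trial, then

1. assembles the plot-record table (one row per plot x stage with CC,
   SDM, LAI, SNC, SNA),
2. appends critical-N, NNI and N-status columns,
3. fits allometric CC–index models per cultivar, per N rate and pooled,
4. runs coincidence F tests across cultivars and N rates (overall and
   per stage),
5. fits per-stage direct CC→NNI models and composes per-stage indirect
   models from the CC→SNC and CC→SDM fits,

and writes every table as CSV/JSON.  Outputs are byte-identical across
reruns with the same configuration and seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import canopy
from .allometry import fit_allometric
from .compare import RegressionComparison, compare_from_dataframe
from .nitrogen import (
    CriticalNCurve, NNIModel, classify_n_status, compose_indirect,
    critical_n, fit_direct, sna_from_sdm_snc,
)
from .simulate import TrialConfig, generate_trial

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "run_pipeline",
    "join_cc_with_sampling",
]

logger = logging.getLogger("wheatcc")

KEY_COLUMNS = ["site", "season", "cultivar", "n_rate_kg_ha",
               "replicate", "stage"]
GROWTH_INDICES = ("sdm_t_ha", "lai", "sna_kg_ha", "snc_pct")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one data source is active: ``synthetic=True`` (the default)
    generates a trial from ``trial``; otherwise ``image_dir``,
    ``meta_csv`` and ``sampling_csv`` must point to real inputs.
    """

    synthetic: bool = True
    trial: TrialConfig = field(default_factory=TrialConfig)
    image_dir: str | None = None
    meta_csv: str | None = None
    sampling_csv: str | None = None
    threshold: "int | str" = 0
    curve: CriticalNCurve = field(default_factory=CriticalNCurve)
    alpha: float = 0.05
    stage_order: tuple[str, ...] = ("Feekes 3", "Feekes 5", "Feekes 6")
    out_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.synthetic:
            if self.image_dir or self.meta_csv or self.sampling_csv:
                raise ValueError(
                    "synthetic mode excludes file inputs: set synthetic=False"
                )
        else:
            if not (self.image_dir and self.meta_csv and self.sampling_csv):
                raise ValueError(
                    "file mode needs image_dir, meta_csv and sampling_csv"
                )

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        """Load a config from a YAML mapping; nested ``trial`` and
        ``curve`` blocks become their dataclasses."""
        raw: Mapping[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "trial" in kwargs and isinstance(kwargs["trial"], Mapping):
            kwargs["trial"] = TrialConfig(**kwargs["trial"])
        if "curve" in kwargs and isinstance(kwargs["curve"], Mapping):
            kwargs["curve"] = CriticalNCurve(**kwargs["curve"])
        if "stage_order" in kwargs:
            kwargs["stage_order"] = tuple(kwargs["stage_order"])
        return cls(**kwargs)


def join_cc_with_sampling(
    cc_table: pd.DataFrame, sampling: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join the CC table with the destructive-sampling table.

    Both tables must carry the plot keys (site, season, cultivar,
    n_rate_kg_ha, replicate, stage); duplicate keys in either side raise
    an integrity error, disjoint keys produce an empty result with a
    reconciliation warning listing orphan keys.  SNA is recomputed as
    10 * SDM * SNC when absent.
    """
    for name, df in (("CC", cc_table), ("sampling", sampling)):
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table lacks key columns {missing}")
        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            raise ValueError(
                f"{name} table has {int(dup.sum())} duplicate plot keys, "
                f"e.g. {df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()}"
            )
    joined = cc_table.merge(sampling, on=KEY_COLUMNS, how="inner")
    if joined.empty and not cc_table.empty and not sampling.empty:
        orphans = pd.concat([
            cc_table[KEY_COLUMNS], sampling[KEY_COLUMNS]
        ]).drop_duplicates()
        warnings.warn(
            "CC and sampling tables share no plot keys; first orphan "
            f"keys: {orphans.head(5).to_dict('records')}",
            stacklevel=2,
        )
    if "sna_kg_ha" not in joined.columns and not joined.empty:
        joined["sna_kg_ha"] = sna_from_sdm_snc(
            joined["sdm_t_ha"].to_numpy(), joined["snc_pct"].to_numpy()
        )
    logger.info("joined %d CC rows with %d sampling rows -> %d records",
                len(cc_table), len(sampling), len(joined))
    return joined


@dataclass
class AnalysisReport:
    """All tables produced by one pipeline run.

    ``fits_by_cultivar`` / ``fits_by_n_rate`` mirror the layout of a
    per-group parameter table (a, b with 95% CIs and R^2);
    ``comparisons`` and ``stage_comparisons`` the coincidence-test
    tables; ``nni_models`` the per-stage direct and indirect CC→NNI
    models.  ``metadata`` echoes the configuration and seed.
    """

    records: pd.DataFrame
    fits_by_cultivar: pd.DataFrame
    fits_by_n_rate: pd.DataFrame
    fits_pooled: pd.DataFrame
    comparisons: pd.DataFrame
    stage_comparisons: pd.DataFrame
    nni_models: pd.DataFrame
    metadata: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "records": self.records,
            "fits_by_cultivar": self.fits_by_cultivar,
            "fits_by_n_rate": self.fits_by_n_rate,
            "fits_pooled": self.fits_pooled,
            "comparisons": self.comparisons,
            "stage_comparisons": self.stage_comparisons,
            "nni_models": self.nni_models,
        }

    def to_json(self) -> str:
        payload = {name: df.to_dict(orient="records")
                   for name, df in self.tables().items()}
        payload["metadata"] = self.metadata
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, out_dir: "str | Path") -> None:
        """Write every table as CSV plus the full report as JSON.

        Floats are serialized with repr-round-tripping precision so
        reruns under the same seed are byte-identical.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(self.to_json())


def _fit_rows(
    df: pd.DataFrame, group_col: str | None
) -> list[dict]:
    """Allometric fits of each growth index on CC, per group level."""
    rows = []
    if group_col is None:
        levels = [("pooled", df)]
    else:
        levels = list(df.groupby(group_col, sort=True, observed=True))
    for level, sub in levels:
        for index in GROWTH_INDICES:
            try:
                res = fit_allometric(sub["cc"], sub[index])
            except (ValueError, np.linalg.LinAlgError):
                continue
            row = {"group": level, "index": index}
            row.update(res.to_dict())
            row["ci95_a_low"], row["ci95_a_high"] = row.pop("ci95_a")
            row["ci95_b_low"], row["ci95_b_high"] = row.pop("ci95_b")
            rows.append(row)
    return rows


def _comparison_row(cmp: RegressionComparison, **labels) -> dict:
    row = dict(labels)
    row.update(cmp.to_dict())
    return row


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the full analysis described in the module docstring.

    Deterministic given ``config`` (including its seed); writes report
    artifacts when ``config.out_dir`` is set and returns the in-memory
    report.
    """
    config.validate()
    if config.synthetic:
        trial_cfg = config.trial
        if trial_cfg.seed != config.seed:
            trial_cfg = TrialConfig(**{**asdict(trial_cfg),
                                       "cultivars": trial_cfg.cultivars,
                                       "seed": config.seed})
        records = generate_trial(trial_cfg)
        logger.info("generated synthetic trial: %d records", len(records))
    else:
        meta = pd.read_csv(config.meta_csv)
        cc_tab = canopy.cc_table(config.image_dir, meta, config.threshold)
        sampling = pd.read_csv(config.sampling_csv)
        records = join_cc_with_sampling(cc_tab, sampling)
        if records.empty:
            raise ValueError("no records after joining CC with sampling")

    stages = [s for s in config.stage_order
              if s in set(records["stage"])] or \
             sorted(records["stage"].unique())
    records = records.copy()
    records["stage"] = pd.Categorical(records["stage"], categories=stages,
                                      ordered=True)
    records = records.sort_values(KEY_COLUMNS, kind="stable",
                                  ignore_index=True)

    # N status columns
    records["nc_pct"] = critical_n(records["sdm_t_ha"].to_numpy(),
                                   config.curve)
    records["nni"] = records["snc_pct"] / records["nc_pct"]
    records["n_status"] = classify_n_status(records["nni"].to_numpy())

    # allometric fits (per cultivar / per N rate / pooled over everything)
    fits_cv = pd.DataFrame(_fit_rows(records, "cultivar"))
    fits_n = pd.DataFrame(_fit_rows(records, "n_rate_kg_ha"))
    fits_pooled_rows = _fit_rows(records, None)
    # pooled-over-stages CC->NNI fit: the cross-stage benchmark for the
    # per-stage models below
    try:
        pooled_nni = fit_allometric(records["cc"], records["nni"])
        row = {"group": "pooled", "index": "nni"}
        row.update(pooled_nni.to_dict())
        row["ci95_a_low"], row["ci95_a_high"] = row.pop("ci95_a")
        row["ci95_b_low"], row["ci95_b_high"] = row.pop("ci95_b")
        fits_pooled_rows.append(row)
    except (ValueError, np.linalg.LinAlgError):
        pass
    fits_pooled = pd.DataFrame(fits_pooled_rows)

    # coincidence tests across cultivars and across N rates, all stages
    cmp_rows = []
    for group_col, label in (("cultivar", "cultivar"),
                             ("n_rate_kg_ha", "n_rate")):
        for index in ("sdm_t_ha", "lai", "sna_kg_ha"):
            try:
                cmp = compare_from_dataframe(
                    records, y=index, x="cc", group=group_col,
                    alpha=config.alpha,
                )
            except ValueError:
                continue
            cmp_rows.append(_comparison_row(cmp, grouping=label,
                                            index=index, stage="all"))
    comparisons = pd.DataFrame(cmp_rows)

    # per-stage: cultivar coincidence for SDM and SNC
    stage_rows = []
    for stage in stages:
        sub = records[records["stage"] == stage]
        for index in ("sdm_t_ha", "snc_pct"):
            try:
                cmp = compare_from_dataframe(
                    sub, y=index, x="cc", group="cultivar",
                    alpha=config.alpha,
                )
            except ValueError:
                continue
            stage_rows.append(_comparison_row(
                cmp, grouping="cultivar", index=index, stage=stage))
    stage_comparisons = pd.DataFrame(stage_rows)

    # per-stage CC->NNI models, direct and indirect
    model_rows = []
    for stage in stages:
        sub = records[records["stage"] == stage]
        if len(sub) < 3:
            continue
        direct = fit_direct(sub["cc"], sub["nni"], stage=stage)
        d_prov = direct.provenance
        model_rows.append({
            "stage": stage, "method": "direct",
            "a_prime": direct.a_prime, "b_prime": direct.b_prime,
            "r2": d_prov.r2, "n": d_prov.n,
            "equation": direct.equation(),
        })
        snc_fit = fit_allometric(sub["cc"], sub["snc_pct"])
        sdm_fit = fit_allometric(sub["cc"], sub["sdm_t_ha"])
        indirect: NNIModel = compose_indirect(
            snc_fit.a, snc_fit.b, sdm_fit.a, sdm_fit.b,
            curve=config.curve, stage=stage,
        )
        model_rows.append({
            "stage": stage, "method": "indirect",
            "a_prime": indirect.a_prime, "b_prime": indirect.b_prime,
            "r2": np.nan, "n": snc_fit.n,
            "equation": indirect.equation(),
        })
    nni_models = pd.DataFrame(model_rows)

    report = AnalysisReport(
        records=records,
        fits_by_cultivar=fits_cv,
        fits_by_n_rate=fits_n,
        fits_pooled=fits_pooled,
        comparisons=comparisons,
        stage_comparisons=stage_comparisons,
        nni_models=nni_models,
        metadata={
            "seed": config.seed,
            "alpha": config.alpha,
            "curve": {"A": config.curve.A, "B": config.curve.B},
            "threshold": config.threshold,
            "synthetic": config.synthetic,
            "n_records": int(len(records)),
        },
    )
    if config.out_dir:
        report.write(config.out_dir)
        logger.info("report written to %s", config.out_dir)
    return report
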