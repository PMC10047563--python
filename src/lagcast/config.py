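"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` ties the generator, release calendar, model specs,
ensemble, validation/test spans and master seed into a single reproducible
run: generate -> backtest (validation, then test) -> score, with every
output file declared in a JSON manifest carrying the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .availability import ReleaseCalendar
from .ensemble import EnsembleSpec
from .evaluation import (
    calibration_curve,
    collect_calibration_pairs,
    cramers_distance,
    max_calibration_deviation,
    pairwise_wilcoxon,
    score_backtest,
    summarize,
)
from .generator import GeneratorConfig, generate_panel
from .models import ModelSpec
from .months import as_index, format_month
from .panel import SurveillancePanel
from .pipeline import run_rolling

log = logging.getLogger("lagcast")

__all__ = ["RunConfig", "run_all", "load_search_terms"]


def load_search_terms() -> pd.DataFrame:
    """Vendored synthetic list of 111 suicide-related search terms.

    A synthetic stand-in for the six-category term list used to query the
    search-trends API (the original appendix is not redistributable);
    category names and counts match the study design: 111 terms over
    suicide_seeking, suicide_prevention, suicide_neutral, mood_anxiety,
    psychosis and stressor_trauma.
    """
    with resources.files("lagcast.data").joinpath("search_terms_synthetic.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class RunConfig:
    """Full configuration of one generate/backtest/score run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    calendar: ReleaseCalendar = field(default_factory=ReleaseCalendar)
    families: Tuple[str, ...] = ("baseline", "auto", "calls", "ght", "calls_ght")
    model_options: dict = field(default_factory=dict)
    include_ensemble: bool = False
    ensemble: Optional[EnsembleSpec] = None
    validation_span: Tuple[Union[int, str], Union[int, str]] = ("2012-01", "2019-12")
    test_span: Tuple[Union[int, str], Union[int, str]] = ("2020-01", "2020-12")
    master_seed: int = 0
    out_dir: Union[str, Path] = "lagcast_run"

    def __post_init__(self):
        self.validation_span = tuple(as_index(v) for v in self.validation_span)
        self.test_span = tuple(as_index(v) for v in self.test_span)
        self.validate()

    def validate(self) -> None:
        v0, v1 = self.validation_span
        t0, t1 = self.test_span
        if v1 < v0 or t1 < t0:
            raise ValueError("spans must be non-empty")
        if t0 <= v1:
            raise ValueError("test span must start after the validation span ends")
        from .models import FAMILY_EXOG

        unknown = [f for f in self.families if f not in FAMILY_EXOG]
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")
        if self.include_ensemble and self.ensemble is None:
            self.ensemble = EnsembleSpec()

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        gen = self.generator
        return {
            "generator": {
                "n_jurisdictions": gen.n_jurisdictions,
                "start_month": format_month(gen.start_month),
                "end_month": format_month(gen.end_month),
                "base_rate": gen.base_rate,
                "trend_slope": (
                    float(gen.trend_slope)
                    if np.isscalar(gen.trend_slope)
                    else [float(v) for v in gen.trend_slope]
                ),
                "seasonal_amplitude": gen.seasonal_amplitude,
                "seasonal_peak_month": gen.seasonal_peak_month,
                "noise_sd": gen.noise_sd,
                "noise_ar": gen.noise_ar,
                "spearman_targets": gen.spearman_targets.tolist(),
                "count_mode": gen.count_mode,
                "call_base_rate": gen.call_base_rate,
                "call_log_sd": gen.call_log_sd,
                "search_logit_sd": gen.search_logit_sd,
                "master_seed": gen.master_seed,
            },
            "calendar": {"proxy_lag": self.calendar.proxy_lag},
            "families": list(self.families),
            "model_options": self.model_options,
            "include_ensemble": self.include_ensemble,
            "validation_span": [format_month(v) for v in self.validation_span],
            "test_span": [format_month(v) for v in self.test_span],
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, raw: dict, out_dir=None) -> "RunConfig":
        gen_raw = dict(raw.get("generator", {}))
        if "trend_slope" in gen_raw and isinstance(gen_raw["trend_slope"], list):
            gen_raw["trend_slope"] = tuple(gen_raw["trend_slope"])
        if "spearman_targets" in gen_raw:
            gen_raw["spearman_targets"] = np.asarray(gen_raw["spearman_targets"], dtype=float)
        cal_raw = raw.get("calendar", {})
        return cls(
            generator=GeneratorConfig(**gen_raw),
            calendar=ReleaseCalendar(
                proxy_lag=cal_raw.get("proxy_lag", 0),
                usable_from=cal_raw.get("usable_from"),
            ),
            families=tuple(raw.get("families", ("baseline", "auto", "calls", "ght", "calls_ght"))),
            model_options=raw.get("model_options", {}),
            include_ensemble=raw.get("include_ensemble", False),
            validation_span=tuple(raw.get("validation_span", ("2012-01", "2019-12"))),
            test_span=tuple(raw.get("test_span", ("2020-01", "2020-12"))),
            master_seed=raw.get("master_seed", 0),
            out_dir=out_dir or raw.get("out_dir", "lagcast_run"),
        )

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), out_dir=out_dir)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def model_specs(self) -> List:
        specs = [ModelSpec(family=f, **self.model_options) for f in self.families]
        if self.include_ensemble:
            specs.append(self.ensemble or EnsembleSpec())
        return specs


def run_all(config: RunConfig) -> dict:
    """Execute generate -> backtest -> score and write all artifacts.

    Returns the run manifest (also written as ``manifest.json``). Partial
    model failures are recorded in the manifest, not fatal; invalid
    configuration raises before anything is written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "outputs": [],
        "skipped_cycles": [],
    }

    def declare(path: Path):
        manifest["outputs"].append(path.name)

    log.info("generating panel: %d jurisdictions", config.generator.n_jurisdictions)
    panel = generate_panel(config.generator)
    panel_path = out / "panel.csv"
    panel.to_csv(panel_path)
    declare(panel_path)

    specs = config.model_specs()
    all_scores = []
    for label, (c0, c1) in (
        ("validation", config.validation_span),
        ("test", config.test_span),
    ):
        log.info("backtest %s: cycles %s..%s", label, format_month(c0), format_month(c1))
        result = run_rolling(
            panel, c0, c1, specs, calendar=config.calendar, master_seed=config.master_seed
        )
        manifest["skipped_cycles"].extend({**f, "period": label} for f in result.failures)
        for kind in ("hindcast", "forecast"):
            qpath = out / f"{label}_{kind}_quantiles.csv"
            result.quantile_frame(kind).to_csv(qpath, index=False)
            declare(qpath)
        scores = score_backtest(result, panel)
        scores.insert(0, "period", label)
        all_scores.append(scores)

        calib_rows = []
        for family in sorted({s.family for s in specs}):
            for kind in ("hindcast", "forecast"):
                qmat, truths = collect_calibration_pairs(result, panel, family, kind)
                cov = calibration_curve(qmat, truths)
                from .quantiles import LEVELS

                for level, c in zip(LEVELS, cov):
                    calib_rows.append(
                        {
                            "family": family,
                            "horizon_kind": kind,
                            "level": level,
                            "coverage": c,
                            "cramers_distance": cramers_distance(cov),
                            "max_abs_deviation": max_calibration_deviation(cov),
                        }
                    )
        cpath = out / f"{label}_calibration.csv"
        pd.DataFrame(calib_rows).to_csv(cpath, index=False)
        declare(cpath)

    scores = pd.concat(all_scores, ignore_index=True)
    scores_out = scores.copy()
    scores_out["generation_month"] = scores_out["generation_month"].map(format_month)
    spath = out / "scores.csv"
    scores_out.to_csv(spath, index=False)
    declare(spath)

    summaries = []
    for period in ("validation", "test"):
        sub = scores[(scores["period"] == period) & (scores["horizon_kind"] == "forecast")]
        if sub.empty:
            continue
        for by in ("overall", "jurisdiction", "year", "month"):
            s = summarize(sub, by=by, reference="baseline" if "baseline" in config.families else None)
            s.insert(0, "period", period)
            s.insert(1, "stratified_by", by)
            summaries.append(s)
        comparisons = pairwise_wilcoxon(sub)
        comparisons.insert(0, "period", period)
        cmp_path = out / f"{period}_comparisons.csv"
        comparisons.to_csv(cmp_path, index=False)
        declare(cmp_path)
    sum_path = out / "summaries.csv"
    pd.concat(summaries, ignore_index=True).to_csv(sum_path, index=False)
    declare(sum_path)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
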