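"""One-command evaluation pipeline: panel in (or synthesized), estimates out.

Runs the full chain — stream loading or synthesis, per-year and pooled event
effects for both event kinds, media/outcome association, baseline comparison
and absolute excess — and writes a JSON estimate bundle, a CSV summary table
and a log.  Every random element is seeded from the single config seed, so a
run is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .baseline_compare import absolute_excess, relative_effect
from .calendar_events import (EVENT_KINDS, EventCalendar,
                              build_event_indicator)
from .cross_stream import fit_media_relation
from .errors import AwareliftError
from .event_effect import (_select_order_with_params, effect_with_ci,
                           estimate_per_year, fit_event_model)
from .streams_io import read_panel, write_panel
from .synthetic_data import default_panel_config, generate_panel


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; exactly one input mode."""
    input_mode: str = "synthesize"          # "synthesize" | "panel_csv"
    panel_path: Optional[str] = None
    span: tuple[str, str] = ("2008-01-01", "2014-12-31")
    event_years: Sequence[int] = tuple(range(2009, 2015))
    event_kinds: Sequence[str] = EVENT_KINDS
    streams: Optional[Sequence[str]] = None   # subset of panel streams; None = all
    media_stream: str = "news"
    media_increase: float = 50.0
    n_draws: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    select_kwargs: dict = field(default_factory=dict)
    output_dir: str = "awarelift_out"

    def __post_init__(self):
        if self.input_mode not in ("synthesize", "panel_csv"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "panel_csv" and not self.panel_path:
            raise ValueError("panel_csv mode requires panel_path")
        if self.input_mode == "synthesize" and self.panel_path:
            raise ValueError("exactly one input mode: synthesize does not take panel_path")
        object.__setattr__(self, "event_years", tuple(int(y) for y in self.event_years))
        object.__setattr__(self, "event_kinds", tuple(self.event_kinds))
        if self.streams is not None:
            object.__setattr__(self, "streams", tuple(self.streams))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "span" in raw:
            raw["span"] = tuple(raw["span"])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["span"] = list(d["span"])
        d["event_years"] = list(d["event_years"])
        d["event_kinds"] = list(d["event_kinds"])
        return d


def _task_seed(master: int, *parts: str) -> int:
    """Stable sub-seed below 2**31 for one estimation task."""
    return (int(master) ^ zlib.crc32(":".join(parts).encode())) % (2 ** 31)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report bundle it also writes."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"awarelift {__version__}",
                      f"config: {json.dumps(config.as_dict(), sort_keys=True)}"]
    failures: list[dict] = []

    # --- input stage
    truth = None
    if config.input_mode == "synthesize":
        synth = default_panel_config(seed=config.seed, span=tuple(config.span),
                                     event_years=config.event_years)
        panel, truth = generate_panel(synth)
        write_panel(panel, outdir / "panel.csv")
        _dump_json({s: {f"{k}:{y}": v for (k, y), v in t.items()}
                    for s, t in truth.items()}, outdir / "truth.json")
        log.append(f"synthesized {len(panel)} streams, seed {config.seed}")
    else:
        panel = read_panel(config.panel_path)
        log.append(f"read panel {config.panel_path}: {len(panel)} streams")
    if config.streams is not None:
        missing = set(config.streams) - set(panel)
        if missing:
            raise ValueError(f"streams not in panel: {sorted(missing)}")
        panel = {k: v for k, v in panel.items() if k in set(config.streams)}

    calendar = EventCalendar.from_years(config.event_years, config.event_kinds)

    # --- estimation stage
    estimates: list[dict] = []
    pooled_fits: dict[tuple[str, str], object] = {}
    pooled_by: dict[tuple[str, str], object] = {}
    per_year_effects: dict[tuple[str, str], dict[int, float]] = {}

    for label in sorted(panel):
        series = panel[label]
        for kind in config.event_kinds:
            days = [d for d in calendar.dates(kind)
                    if series.dates[0] <= pd.Timestamp(d) <= series.dates[-1]]
            key = (label, kind)
            per_year_effects[key] = {}
            try:
                if len(days) < 2:
                    raise ValueError(f"pooled estimate needs >= 2 {kind} events "
                                     f"in span, found {len(days)}")
                ind = build_event_indicator(series.dates, calendar, kind)
                order, warm = _select_order_with_params(series, ind,
                                                        **config.select_kwargs)
                fit = fit_event_model(series, ind, order, event_kind=kind,
                                      start_params=warm)
                est = effect_with_ci(fit, series, days, n_draws=config.n_draws,
                                     alpha=config.alpha,
                                     seed=_task_seed(config.seed, label, kind, "pooled"),
                                     scope="pooled")
                estimates.append(est.as_record())
                pooled_fits[key] = fit
                pooled_by[key] = est
            except (AwareliftError, ValueError) as exc:
                failures.append({"stage": "pooled", "stream": label,
                                 "event_kind": kind, "error": str(exc)})
            for year in config.event_years:
                try:
                    est = estimate_per_year(
                        series, calendar, year, kind, n_draws=config.n_draws,
                        alpha=config.alpha,
                        seed=_task_seed(config.seed, label, kind, str(year)),
                        select_kwargs=config.select_kwargs)
                    estimates.append(est.as_record())
                    per_year_effects[key][year] = est.effect
                except (AwareliftError, ValueError) as exc:
                    failures.append({"stage": "per_year", "stream": label,
                                     "event_kind": kind, "year": year,
                                     "error": str(exc)})

    # --- cross-stream stage (campaign effects, percent points)
    relations: list[dict] = []
    media_key = (config.media_stream, "campaign")
    media_years = per_year_effects.get(media_key, {})
    outcome_streams = [s for s in sorted(panel) if s != config.media_stream]
    if config.media_stream not in panel or not outcome_streams:
        log.append("cross-stream stage skipped: needs the media stream plus at "
                   "least one outcome stream")
        outcome_streams = []
    for label in outcome_streams:
        out_years = per_year_effects.get((label, "campaign"), {})
        shared = sorted(set(media_years) & set(out_years))
        if len(shared) < 3:
            failures.append({"stage": "cross_stream", "stream": label,
                             "error": f"only {len(shared)} matched years"})
            continue
        try:
            rel = fit_media_relation(
                [media_years[y] * 100 for y in shared],
                [out_years[y] * 100 for y in shared],
                outcome=label, media_increase=config.media_increase,
                n_draws=config.n_draws, alpha=config.alpha,
                seed=_task_seed(config.seed, label, "relate"))
            relations.append(rel.as_record())
        except (AwareliftError, ValueError) as exc:
            failures.append({"stage": "cross_stream", "stream": label,
                             "error": str(exc)})

    # --- baseline comparison stage
    comparisons: list[dict] = []
    excesses: list[dict] = []
    for label in sorted(panel):
        camp = pooled_by.get((label, "campaign"))
        base = pooled_by.get((label, "baseline"))
        if camp is not None and base is not None:
            comparisons.append(relative_effect(camp, base).as_record())
        for kind in config.event_kinds:
            fit = pooled_fits.get((label, kind))
            if fit is None:
                continue
            days = [d for d in calendar.dates(kind)
                    if panel[label].dates[0] <= pd.Timestamp(d) <= panel[label].dates[-1]]
            excesses.append(absolute_excess(panel[label], fit, days).as_record())

    # --- report stage
    bundle = {
        "estimates": estimates,
        "cross_stream": relations,
        "baseline_compare": {"relative": comparisons, "excess": excesses},
        "failures": failures,
        "seeds": {"master": config.seed},
        "version": __version__,
    }
    _dump_json(bundle, outdir / "estimates.json")
    summary = pd.DataFrame([{k: r[k] for k in ("stream", "event_kind", "scope",
                                               "effect", "ci_low", "ci_high",
                                               "observed", "counterfactual")}
                            for r in estimates])
    summary.to_csv(outdir / "summary.csv", index=False)
    log.append(f"{len(estimates)} estimates, {len(failures)} failures")
    for f in failures:
        log.append(f"FAILED {json.dumps(f, sort_keys=True)}")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return bundle
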