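"""Run configuration, analysis driver and result writing.

A run is described by a YAML config:

.. code-block:: yaml

    data: panel.csv
    regimes:
      - {kind: static, vector: [0,0,0,0,0,0,0], label: never_feed}
      - {kind: static, vector: [0,0,1,1,1,1,1], label: feed_from_day_3}
      - {kind: delayed_start, start_day: 2, label: feed_by_day_3}
      - {kind: dynamic, covariate: vent, feed_when_value: 0, label: feed_off_vent}
    t_star: [5]
    estimators: [naive, iptw, gcomp, tmle]
    nuisance:
      library: [intercept, logit_main, logit_interact, logit_l1]
      folds: 10
      seed: 7
      markov_order: 2
      g_lower_bound: null
    out: results/

Every default is echoed into the run log so a run is reproducible from its
emitted config and seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import survival_curve
from .exceptions import ConfigError
from .learners import default_library
from .panel import PanelData, read_panel_csv
from .regimes import Regime, delayed_start_regime, dynamic_rule_regime, follower_counts, static_regime

_ESTIMATORS = ("naive", "iptw", "gcomp", "tmle")


@dataclass
class NuisanceConfig:
    library: list = field(default_factory=lambda: [s.name for s in default_library()])
    folds: int = 10
    seed: int = 0
    markov_order: int | str = 2
    q_markov_order: int | str = "full"
    g_lower_bound: float | None = None

    def validate(self):
        if self.folds < 2:
            raise ConfigError("nuisance.folds must be >= 2")


@dataclass
class RunConfig:
    data: str
    regimes: list[dict]
    t_star: list[int]
    estimators: list[str] = field(default_factory=lambda: list(_ESTIMATORS))
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    out: str = "results"
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            nuis = NuisanceConfig(**raw.get("nuisance", {}))
            cfg = cls(
                data=raw["data"],
                regimes=raw["regimes"],
                t_star=[int(t) for t in np.atleast_1d(raw.get("t_star", []))],
                estimators=list(raw.get("estimators", _ESTIMATORS)),
                nuisance=nuis,
                out=raw.get("out", "results"),
                verbosity=int(raw.get("verbosity", 1)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed run config: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self):
        self.nuisance.validate()
        for e in self.estimators:
            if e not in _ESTIMATORS:
                raise ConfigError(f"unknown estimator {e!r}")
        labels = [r.get("label") for r in self.regimes]
        if len(set(labels)) != len(labels):
            raise ConfigError("regime labels must be unique")

    def build_regimes(self, T_plus_1: int) -> list[Regime]:
        return [build_regime(r, T_plus_1) for r in self.regimes]

    def to_dict(self) -> dict:
        d = {
            "data": self.data,
            "regimes": self.regimes,
            "t_star": self.t_star,
            "estimators": self.estimators,
            "nuisance": {
                "library": list(self.nuisance.library),
                "folds": self.nuisance.folds,
                "seed": self.nuisance.seed,
                "markov_order": self.nuisance.markov_order,
                "q_markov_order": self.nuisance.q_markov_order,
                "g_lower_bound": self.nuisance.g_lower_bound,
            },
            "out": self.out,
            "verbosity": self.verbosity,
        }
        return d


def build_regime(spec: dict, T_plus_1: int) -> Regime:
    kind = spec.get("kind")
    label = spec.get("label")
    if kind == "static":
        vec = spec["vector"]
        if len(vec) != T_plus_1:
            raise ConfigError(
                f"static vector for {label!r} has length {len(vec)}, expected {T_plus_1}"
            )
        return static_regime(vec, label)
    if kind == "delayed_start":
        return delayed_start_regime(int(spec["start_day"]), T_plus_1, label)
    if kind == "dynamic":
        return dynamic_rule_regime(spec["covariate"], int(spec["feed_when_value"]), label)
    raise ConfigError(f"unknown regime kind {kind!r}")


@dataclass
class ResultsBundle:
    estimates: pd.DataFrame
    follower_table: pd.DataFrame
    config_echo: dict
    log_lines: list[str]
    ic_values: pd.DataFrame | None = None


def run_analysis(config: RunConfig, panel: PanelData | None = None) -> ResultsBundle:
    """Fit everything the config requests and collect outputs.

    Nuisances are only fitted when an adjusted estimator asks for them
    (a naive-only run performs no model fitting at all).
    """
    log: list[str] = []
    if panel is None:
        panel = read_panel_csv(config.data)
    log.append(f"panel: n={panel.n}, periods={panel.T_plus_1}")
    regimes = config.build_regimes(panel.T_plus_1)
    nuis = config.nuisance
    ic_collector: dict = {}
    table = survival_curve(
        panel,
        regimes,
        estimators=tuple(config.estimators),
        t_range=config.t_star,
        library=list(nuis.library),
        g_library=list(nuis.library),
        folds=nuis.folds,
        seed=nuis.seed,
        markov_order=nuis.q_markov_order,
        g_markov_order=nuis.markov_order,
        g_lower_bound=nuis.g_lower_bound,
        ic_collector=ic_collector,
    )
    ic_frame = None
    if ic_collector:
        ic_frame = pd.DataFrame(
            {f"{lab}|t{t}|{est}": ic for (lab, t, est), ic in ic_collector.items()}
        )
        ic_frame.index.name = "subject"
    for _, row in table.iterrows():
        log.append(
            f"{row['regime']} t*={row['t_star']} {row['estimator']}: "
            f"psi={row['psi']:.4f} followers={row['n_followers']} "
            f"min_cum_g={'' if pd.isna(row['min_cum_g']) else format(row['min_cum_g'], '.4f')}"
        )
    ftab = follower_counts(panel, regimes)
    return ResultsBundle(
        estimates=table,
        follower_table=ftab,
        config_echo=config.to_dict(),
        log_lines=log,
        ic_values=ic_frame,
    )


def write_results(bundle: ResultsBundle, outdir, plots: bool = False) -> list[Path]:
    """Write estimates.csv, diagnostics, a JSON summary and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    est_path = outdir / "estimates.csv"
    cols = ["regime", "t_star", "estimator", "psi", "se", "ci_low", "ci_high",
            "n_followers", "min_cum_g"]
    est = bundle.estimates.reindex(columns=cols)
    est.to_csv(est_path, index=False)
    written.append(est_path)
    diag_path = outdir / "follower_counts.csv"
    bundle.follower_table.to_csv(diag_path)
    written.append(diag_path)
    if bundle.ic_values is not None:
        ic_path = outdir / "ic_values.csv"
        bundle.ic_values.to_csv(ic_path)
        written.append(ic_path)
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(
            {"config": bundle.config_echo,
             "estimates": json.loads(est.to_json(orient="records"))},
            fh, indent=2,
        )
    written.append(summary_path)
    log_path = outdir / "run.log"
    log_path.write_text("\n".join(bundle.log_lines) + "\n")
    written.append(log_path)
    if plots and len(bundle.estimates):
        written.append(plot_curves(bundle.estimates, outdir / "curves.png"))
    return written


def plot_curves(estimates: pd.DataFrame, path) -> Path:
    """Cumulative-incidence panel per estimator: estimate vs day with CI bars
    per regime (no bars for g-computation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ests = list(estimates["estimator"].unique())
    fig, axes = plt.subplots(1, len(ests), figsize=(4 * len(ests), 3.5), squeeze=False)
    for ax, est in zip(axes[0], ests):
        sub = estimates[estimates["estimator"] == est]
        for reg, grp in sub.groupby("regime"):
            grp = grp.sort_values("t_star")
            if grp["se"].notna().any():
                yerr = np.vstack([
                    grp["psi"] - grp["ci_low"], grp["ci_high"] - grp["psi"],
                ])
                ax.errorbar(grp["t_star"], grp["psi"], yerr=yerr, marker="o",
                            capsize=3, label=reg)
            else:
                ax.plot(grp["t_star"], grp["psi"], marker="o", label=reg)
        ax.set_title(est)
        ax.set_xlabel("day")
        ax.set_ylim(0, 1)
    axes[0][0].set_ylabel("P(discharged alive)")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
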