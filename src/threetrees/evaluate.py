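"""Error metrics and the replicated simulation study runner.

Four mean-squared-error criteria summarise a fitted model on a within-
cluster train/test split:

* ``mse`` / ``pmse`` — fixed-effects-only predictions on the training /
  test half (for 3Trees fits the tree-region terms are part of the fixed
  effects);
* ``clus_mse`` / ``clus_pmse`` — the same predictions plus the estimated
  cluster random intercepts (BLUPs).

Each metric averages squared errors over its own set's row count.
:func:`run_study` replicates generate -> split -> fit -> score over seeded
replications for any combination of simulation settings and methods, and
emits "mean (SD)" summary tables plus parameter-bias tables; raw per-rep
arrays are always kept so no downstream check depends on rounding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import HierarchicalDataset, split_within_cluster
from .evtree import EvolutionConfig
from .lmm import MixedFit, fit_mixed, predict_mixed
from .model import ThreeTreesConfig, ThreeTreesFit, fit_3trees, predict_3trees
from .simulate import SIZE_GRID, ScenarioParams, make_setting

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "StudyResult",
    "compute_metrics",
    "run_study",
    "sample_size_curves",
    "fit_method",
    "METHOD_NAMES",
    "STUDY_EVOLUTION",
]

#: reduced evolution budget used inside replicated studies (full defaults in
#: EvolutionConfig are meant for one-shot fits)
STUDY_EVOLUTION = EvolutionConfig(
    population_size=20, max_iterations=120, stagnation_window=25
)

METHOD_NAMES = ("lmm", "cart", "cart-cp1e-4", "ctree", "evtree")

_PARAM_TERMS = {
    "beta0": "(Intercept)",
    "beta1": "x1",
    "beta2": "x2",
    "beta3": "x3",
    "beta4": "x4",
    "gamma1": "z1",
    "gamma2": "z2",
    "gamma3": "z3",
}


@dataclass
class MetricsReport:
    mse: float
    clus_mse: float
    pmse: Optional[float] = None
    clus_pmse: Optional[float] = None


class _FittedLMM:
    """Plain linear mixed model wrapper with the common predict interface."""

    def __init__(self, fit: MixedFit, x_names, z_names):
        self.fit = fit
        self.x_names = list(x_names)
        self.z_names = list(z_names)

    @staticmethod
    def fit(train: HierarchicalDataset) -> "_FittedLMM":
        W = np.column_stack([np.ones(train.n_total), train.X, train.Z])
        names = ["(Intercept)", *train.x_names, *train.z_names]
        return _FittedLMM(
            fit_mixed(W, train.y, train.cluster, names), train.x_names, train.z_names
        )

    def predict(self, data: HierarchicalDataset, include_random: bool = False):
        W = np.column_stack([np.ones(data.n_total), data.X, data.Z])
        return predict_mixed(self.fit, W, data.cluster, include_random)

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def sigma_u2(self) -> float:
        return self.fit.sigma_u2

    @property
    def sigma_e2(self) -> float:
        return self.fit.sigma_e2


class _FittedThreeTrees:
    def __init__(self, fit: ThreeTreesFit):
        self.fit = fit

    def predict(self, data: HierarchicalDataset, include_random: bool = False):
        return predict_3trees(self.fit, data, include_random=include_random)

    @property
    def params(self) -> pd.Series:
        return self.fit.final_fit.params

    @property
    def sigma_u2(self) -> float:
        return self.fit.final_fit.sigma_u2

    @property
    def sigma_e2(self) -> float:
        return self.fit.final_fit.sigma_e2


def fit_method(name: str, train: HierarchicalDataset, seed: Optional[int] = None):
    """Fit one named method on a training set.

    Methods: ``lmm``; ``cart`` (3Trees, cp=0); ``cart-cp1e-4`` (3Trees,
    cp=1e-4); ``ctree`` (3Trees, alpha=0.05); ``evtree`` (3Trees with the
    reduced study evolution budget).  All tree engines use maxdepth 3,
    nmin 10.
    """
    if name == "lmm":
        return _FittedLMM.fit(train)
    if name == "cart":
        cfg = ThreeTreesConfig(engine="cart", cp=0.0, seed=seed)
    elif name == "cart-cp1e-4":
        cfg = ThreeTreesConfig(engine="cart", cp=1e-4, seed=seed)
    elif name == "ctree":
        cfg = ThreeTreesConfig(engine="ctree", alpha=0.05, seed=seed)
    elif name == "evtree":
        cfg = ThreeTreesConfig(engine="evtree", evolution=STUDY_EVOLUTION, seed=seed)
    else:
        raise ValueError(f"unknown method {name!r}; expected one of {METHOD_NAMES}")
    return _FittedThreeTrees(fit_3trees(train, cfg))


def compute_metrics(
    model, train: HierarchicalDataset, test: Optional[HierarchicalDataset] = None
) -> MetricsReport:
    """The four error criteria for a fitted model on a train/test split.

    ``model`` is anything with a ``predict(data, include_random=...)``
    method; a bare :class:`ThreeTreesFit` is wrapped automatically.
    """
    if isinstance(model, ThreeTreesFit):
        model = _FittedThreeTrees(model)

    def msq(data: HierarchicalDataset, include_random: bool) -> float:
        pred = model.predict(data, include_random=include_random)
        return float(np.mean((data.y - pred) ** 2))

    report = MetricsReport(mse=msq(train, False), clus_mse=msq(train, True))
    if test is not None and test.n_total > 0:
        report.pmse = msq(test, False)
        report.clus_pmse = msq(test, True)
    return report


@dataclass
class StudyResult:
    """Raw per-replication results plus summary builders."""

    raw: pd.DataFrame
    true_params: dict  # setting label -> ScenarioParams
    n_reps: int
    master_seed: int

    _METRICS = ("mse", "clus_mse", "pmse", "clus_pmse")

    def summary(self) -> pd.DataFrame:
        """Per setting x method: 'mean (SD)' cells for the four criteria."""
        rows = []
        for (setting, method), grp in self.raw.groupby(
            ["setting", "method"], sort=False
        ):
            row: dict = {"setting": setting, "method": method, "n_reps": len(grp)}
            for metric in self._METRICS:
                vals = grp[metric].dropna()
                if len(vals) == 0:
                    row[metric] = "NA"
                elif len(vals) == 1:
                    row[metric] = f"{vals.iloc[0]:.3f} (NA)"
                else:
                    row[metric] = f"{vals.mean():.3f} ({vals.std(ddof=1):.3f})"
            rows.append(row)
        return pd.DataFrame(rows)

    def metric_mean(self, setting: str, method: str, metric: str) -> float:
        grp = self.raw[(self.raw.setting == setting) & (self.raw.method == method)]
        return float(grp[metric].mean())

    def bias_table(self) -> pd.DataFrame:
        """Mean, SD and absolute bias of every fixed-effect estimate."""
        rows = []
        for (setting, method), grp in self.raw.groupby(
            ["setting", "method"], sort=False
        ):
            params = self.true_params[setting]
            truth = dict(
                zip(
                    _PARAM_TERMS,
                    [*params.beta, *params.gamma],
                )
            )
            for pname, true_val in truth.items():
                vals = grp[pname].dropna()
                if len(vals) == 0:
                    continue
                rows.append(
                    {
                        "setting": setting,
                        "method": method,
                        "parameter": pname,
                        "true_value": true_val,
                        "mean": vals.mean(),
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                        "abs_bias": abs(vals.mean() - true_val),
                    }
                )
        return pd.DataFrame(rows)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.raw.to_csv(out / "replications.csv", index=False)
        self.summary().to_csv(out / "summary_metrics.csv", index=False)
        self.bias_table().to_csv(out / "summary_bias.csv", index=False)


def _rep_seeds(master_seed: int, rep: int, k: int) -> list[int]:
    """k per-replication seeds keyed on (master, rep); each below 2**31."""
    state = np.random.SeedSequence([int(master_seed), int(rep)]).generate_state(k)
    return [int(s % (2**31)) for s in state]


def _setting_label(s: dict) -> str:
    return (
        f"{s['scenario']}-icc_{s.get('icc_level', 'high')}"
        f"-rho_{s.get('corr_level', 'high')}-J{s.get('J', 70)}-nj{s.get('nj', 50)}"
    )


def run_study(
    settings: Sequence[dict],
    methods: Sequence[str],
    n_reps: int = 100,
    master_seed: int = 0,
    out_dir=None,
    train_fraction: float = 0.5,
) -> StudyResult:
    """Replicated generate / split / fit / score study.

    ``settings`` is a list of dicts with keys ``scenario`` and optionally
    ``icc_level``, ``corr_level``, ``J``, ``nj``.  A failed replication of a
    method is logged and skipped; summaries flag the reduced cell counts via
    ``n_reps``.
    """
    records = []
    true_params: dict = {}
    for setting in settings:
        label = _setting_label(setting)
        for rep in range(n_reps):
            data_seed, split_seed, fit_seed = _rep_seeds(master_seed, rep, 3)
            data, params = make_setting(
                setting["scenario"],
                setting.get("icc_level", "high"),
                setting.get("corr_level", "high"),
                setting.get("J", 70),
                setting.get("nj", 50),
                seed=data_seed,
            )
            true_params[label] = params
            train, test = split_within_cluster(data, train_fraction, split_seed)
            for m_idx, method in enumerate(methods):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model = fit_method(method, train, seed=fit_seed + m_idx)
                    metrics = compute_metrics(model, train, test)
                except Exception as exc:
                    logger.warning(
                        "rep %d of %s failed for method %s: %s", rep, label, method, exc
                    )
                    continue
                rec = {
                    "setting": label,
                    "scenario": setting["scenario"],
                    "icc_level": setting.get("icc_level", "high"),
                    "corr_level": setting.get("corr_level", "high"),
                    "J": setting.get("J", 70),
                    "nj": setting.get("nj", 50),
                    "rep": rep,
                    "seed": data_seed,
                    "method": method,
                    "mse": metrics.mse,
                    "clus_mse": metrics.clus_mse,
                    "pmse": metrics.pmse,
                    "clus_pmse": metrics.clus_pmse,
                    "sigma_u2": model.sigma_u2,
                    "sigma_e2": model.sigma_e2,
                }
                for pname, term in _PARAM_TERMS.items():
                    rec[pname] = (
                        float(model.params[term]) if term in model.params.index else np.nan
                    )
                records.append(rec)
    result = StudyResult(
        raw=pd.DataFrame(records),
        true_params=true_params,
        n_reps=n_reps,
        master_seed=master_seed,
    )
    if out_dir is not None:
        result.save(out_dir)
    return result


def sample_size_curves(
    scenario: str = "M2",
    methods: Sequence[str] = ("lmm", "cart", "evtree"),
    sizes: Sequence[int] = (750, 1500, 3500),
    n_reps: int = 10,
    master_seed: int = 0,
    icc_level: str = "high",
    corr_level: str = "high",
) -> pd.DataFrame:
    """Prediction error and bias versus total sample size (long format).

    Sizes are looked up in the standard grid (total -> (J, nj)); custom
    ``(J, nj)`` tuples are also accepted.  Emits per-size means of PMSE and
    clusPMSE and absolute biases of beta1, gamma1, sigma_u and sigma_e.
    """
    rows = []
    for size in sizes:
        if isinstance(size, tuple):
            J, nj = size
        else:
            if size not in SIZE_GRID:
                raise ValueError(f"size {size} not in grid {sorted(SIZE_GRID)}")
            J, nj = SIZE_GRID[size]
        setting = {
            "scenario": scenario,
            "icc_level": icc_level,
            "corr_level": corr_level,
            "J": J,
            "nj": nj,
        }
        result = run_study([setting], methods, n_reps, master_seed)
        params = next(iter(result.true_params.values()))
        for method, grp in result.raw.groupby("method", sort=False):
            rows.append(
                {
                    "n_total": J * nj,
                    "J": J,
                    "nj": nj,
                    "method": method,
                    "pmse": grp["pmse"].mean(),
                    "clus_pmse": grp["clus_pmse"].mean(),
                    "abs_bias_beta1": abs(grp["beta1"].mean() - params.beta[1]),
                    "abs_bias_gamma1": abs(grp["gamma1"].mean() - params.gamma[0]),
                    "abs_bias_sigma_u": abs(
                        np.sqrt(grp["sigma_u2"]).mean() - np.sqrt(params.sigma_u2)
                    ),
                    "abs_bias_sigma_e": abs(
                        np.sqrt(grp["sigma_e2"]).mean() - np.sqrt(params.sigma_e2)
                    ),
                    "n_reps": len(grp),
                }
            )
    return pd.DataFrame(rows)
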