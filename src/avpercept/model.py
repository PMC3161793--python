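"""Maximum-likelihood fit and MAP inference for the perception network.

The joint law factorizes as
``P(S) P(M) P(XP) P(XS|M) P(XHAT|S,XP,XS) P(T|S,XS)``:
multinomial tables for the discrete factors, a Gaussian for the
normalized localization per parent configuration, and a log-normal for
the decision time (log T is Gaussian).  All parameters are plug-in
maximum-likelihood estimates; parent configurations with fewer than two
observations are flagged and inference on them is refused rather than
smoothed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import binning_for
from .structure import VARIABLES, make_binnings

__all__ = ["FittedModel", "fit", "map_percept", "map_decision_time",
           "log_likelihood", "EXPECTED_FACTORIZATION"]

#: Parent sets of the elicited network (M -> XS resolving the undirected edge).
EXPECTED_FACTORIZATION = [
    ("S", ()),
    ("M", ()),
    ("XP", ()),
    ("XS", ("M",)),
    ("XHAT", ("S", "XP", "XS")),
    ("T", ("S", "XS")),
]

_DISCRETE = ("S", "M", "XP", "XS")
MIN_CELL_COUNT = 2


@dataclass
class FittedModel:
    """CPD tables of the fitted network."""

    factorization: list
    binnings: dict
    multinomials: dict    # var -> {parent_config: probs over var bins}
    gaussian: dict        # parent_config -> (mean deg, sd deg, n)
    lognormal: dict       # parent_config -> (mu log-s, sigma log-s, n)
    gaussian_parents: tuple = ("S", "XP", "XS")
    time_parents: tuple = ("S", "XS")
    flagged: list = field(default_factory=list)

    def parent_key(self, parents: tuple, values: dict) -> tuple:
        key = []
        for p in parents:
            v = values[p]
            key.append(int(self.binnings[p].assign([v])[0]))
        return tuple(key)

    # -- serialization ------------------------------------------------------

    def to_text(self, path) -> None:
        def enc(d):
            return {",".join(map(str, k)): list(v) for k, v in d.items()}
        payload = {
            "factorization": [[v, list(p)] for v, p in self.factorization],
            "multinomials": {v: enc(t) for v, t in self.multinomials.items()},
            "gaussian": enc(self.gaussian),
            "lognormal": enc(self.lognormal),
            "gaussian_parents": list(self.gaussian_parents),
            "time_parents": list(self.time_parents),
            "flagged": self.flagged,
            "t_max": self.binnings["T"].edges[-1],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_text(cls, path) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)

        def dec(d, cast=tuple):
            out = {}
            for k, v in d.items():
                key = tuple(int(x) for x in k.split(",")) if k else ()
                out[key] = cast(v)
            return out
        binnings = {k: binning_for(k, t_max=payload["t_max"]) if k == "T"
                    else binning_for(k) for k in VARIABLES}
        return cls(
            factorization=[(v, tuple(p)) for v, p in payload["factorization"]],
            binnings=binnings,
            multinomials={v: dec(t, np.asarray)
                          for v, t in payload["multinomials"].items()},
            gaussian=dec(payload["gaussian"]),
            lognormal=dec(payload["lognormal"]),
            gaussian_parents=tuple(payload["gaussian_parents"]),
            time_parents=tuple(payload["time_parents"]),
            flagged=[tuple(f) if isinstance(f, list) else f
                     for f in payload["flagged"]],
        )


def _bin_columns(table: pd.DataFrame, binnings: dict) -> dict:
    return {k: binnings[k].assign(table[VARIABLES[k]].to_numpy(dtype=float))
            for k in VARIABLES}


def fit(table: pd.DataFrame, factorization=None,
        binnings: dict | None = None) -> FittedModel:
    """Maximum-likelihood fit of every factor on a preprocessed table.

    Multinomials are empirical bin frequencies; the XHAT factor is the
    sample mean/SD of ``response_norm`` per parent configuration; the T
    factor the sample mean/SD of ``log(decision_time)``.
    """
    factorization = factorization or EXPECTED_FACTORIZATION
    binnings = binnings or make_binnings(table)
    if "response_norm" not in table.columns:
        raise KeyError("table must be normalized first (response_norm missing)")
    idx = _bin_columns(table, binnings)
    fac = dict(factorization)
    flagged = []

    multinomials = {}
    for var in _DISCRETE:
        parents = fac.get(var, ())
        k = binnings[var].n_bins
        tab = {}
        if parents:
            keys = np.stack([idx[p] for p in parents], axis=1)
            for key in np.unique(keys, axis=0):
                mask = (keys == key).all(axis=1)
                counts = np.bincount(idx[var][mask], minlength=k).astype(float)
                tab[tuple(int(x) for x in key)] = counts / counts.sum()
        else:
            counts = np.bincount(idx[var], minlength=k).astype(float)
            tab[()] = counts / counts.sum()
        multinomials[var] = tab

    def continuous_factor(var, column, log_scale):
        parents = fac.get(var, ())
        vals = table[column].to_numpy(dtype=float)
        if log_scale:
            if (vals <= 0).any():
                raise ValueError(f"{column} must be positive for a log-normal fit")
            vals = np.log(vals)
        out = {}
        keys = (np.stack([idx[p] for p in parents], axis=1) if parents
                else np.zeros((len(vals), 0), dtype=int))
        for key in np.unique(keys, axis=0):
            mask = (keys == key).all(axis=1) if parents else np.ones(len(vals), bool)
            cell = vals[mask]
            cfg = tuple(int(x) for x in key)
            if cell.size < MIN_CELL_COUNT:
                flagged.append((var, cfg))
                continue
            sd = float(cell.std(ddof=1))
            out[cfg] = (float(cell.mean()), max(sd, 1e-12), int(cell.size))
        return out, parents

    gaussian, g_parents = continuous_factor("XHAT", "response_norm", False)
    lognormal, t_parents = continuous_factor("T", "decision_time", True)

    return FittedModel(
        factorization=list(factorization), binnings=binnings,
        multinomials=multinomials, gaussian=gaussian, lognormal=lognormal,
        gaussian_parents=g_parents, time_parents=t_parents, flagged=flagged)


def _lookup(model: FittedModel, table: dict, var: str, parents: tuple,
            values: dict):
    key = model.parent_key(parents, values)
    if (var, key) in model.flagged:
        raise ValueError(f"configuration {key} for {var} is flagged (too few observations)")
    if key not in table:
        raise KeyError(f"unseen parent configuration {key} for {var}")
    return table[key]


def map_percept(model: FittedModel, s: int, xp: float, xs: float) -> float:
    """MAP localization: the mode (= mean) of the Gaussian XHAT factor."""
    mean, _sd, _n = _lookup(model, model.gaussian, "XHAT",
                            model.gaussian_parents,
                            {"S": s, "XP": xp, "XS": xs})
    return mean


def map_decision_time(model: FittedModel, s: int, xs: float,
                      convention: str = "mode") -> float:
    """MAP decision time from the log-normal T factor.

    ``convention="mode"`` returns the mode of the log-normal density in
    seconds, ``exp(mu - sigma^2)``; ``convention="log_mode"`` returns
    ``exp(mu)``, the mode on the log scale (= the median of T).
    """
    mu, sigma, _n = _lookup(model, model.lognormal, "T",
                            model.time_parents, {"S": s, "XS": xs})
    if convention == "mode":
        return float(np.exp(mu - sigma**2))
    if convention == "log_mode":
        return float(np.exp(mu))
    raise ValueError("convention must be 'mode' or 'log_mode'")


_LOG_SQRT_2PI = 0.5 * math.log(2 * math.pi)


def log_likelihood(model: FittedModel, table: pd.DataFrame):
    """Per-trial sum of log densities under the factorization.

    Returns ``(total, n_flagged)`` where ``n_flagged`` counts trials that
    hit a flagged or unseen configuration (they contribute nothing to the
    total and are reported rather than silently penalized).
    """
    idx = _bin_columns(table, model.binnings)
    fac = dict(model.factorization)
    n = len(table)
    total = 0.0
    flagged_trials = np.zeros(n, dtype=bool)

    for var in _DISCRETE:
        parents = fac.get(var, ())
        tab = model.multinomials[var]
        keys = (np.stack([idx[p] for p in parents], axis=1) if parents
                else np.zeros((n, 0), dtype=int))
        for i in range(n):
            probs = tab.get(tuple(int(x) for x in keys[i]))
            if probs is None or probs[idx[var][i]] <= 0:
                flagged_trials[i] = True
            else:
                total += math.log(probs[idx[var][i]])

    xhat = table["response_norm"].to_numpy(dtype=float)
    logt = np.log(table["decision_time"].to_numpy(dtype=float))
    for var, cont_table, parents, vals, jac in (
            ("XHAT", model.gaussian, model.gaussian_parents, xhat, None),
            ("T", model.lognormal, model.time_parents, logt, logt)):
        keys = np.stack([idx[p] for p in parents], axis=1)
        for i in range(n):
            cfg = tuple(int(x) for x in keys[i])
            if (var, cfg) in model.flagged or cfg not in cont_table:
                flagged_trials[i] = True
                continue
            mu, sd, _ = cont_table[cfg]
            total += (-_LOG_SQRT_2PI - math.log(sd)
                      - 0.5 * ((vals[i] - mu) / sd) ** 2)
            if jac is not None:
                total -= jac[i]  # d(log t)/dt Jacobian of the log-normal
    return total, int(flagged_trials.sum())
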