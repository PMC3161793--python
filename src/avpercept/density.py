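"""Discretization and plug-in density estimation for the six model variables.

Every random variable is discretized with a fixed histogram scheme:

* XP  — 5 bins of width 5 centered on the primary positions;
* XS  — 9 width-5 bins centered on -20..20 plus one sentinel bin for the
  unimodal case;
* XHAT — 15 bins: 13 width-5 bins centered on -30..30 and two boundary
  bins covering [-40, -32.5) and (32.5, 40] where data are sparse;
* S, M — two bins centered on 0 and 1;
* T   — width-0.2 bins centered on 0.1 + 0.2k covering [0, t_max], plus
  one overflow bin for the few larger values.

Probabilities are maximum-likelihood plug-in estimates (counts / n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BinningScheme",
    "HistogramDensity",
    "binning_for",
    "histogram",
    "joint_histogram",
    "entropy",
]

KINDS = ("XP", "XS", "XHAT", "S", "M", "T")


@dataclass(frozen=True)
class BinningScheme:
    """Mapping from variable values to histogram bin indices."""

    kind: str
    edges: tuple          # interior edges, strictly increasing
    centers: tuple        # representative value per bin (None for special bins)
    sentinel_index: int | None = None  # XS only: bin for the unimodal sentinel
    overflow_index: int | None = None  # T only: bin above the regular grid

    @property
    def n_bins(self) -> int:
        n = len(self.edges) - 1
        if self.sentinel_index is not None:
            n += 1
        if self.overflow_index is not None:
            n += 1
        return n

    def assign(self, values) -> np.ndarray:
        """Map values to bin indices; raises on unmappable values."""
        v = np.asarray(values, dtype=float)
        idx = np.empty(v.shape, dtype=np.intp)
        nan = np.isnan(v)
        if nan.any():
            if self.sentinel_index is None:
                raise ValueError(f"NaN not mappable for kind {self.kind}")
            idx[nan] = self.sentinel_index
        ok = ~nan
        vv = v[ok]
        edges = np.asarray(self.edges)
        # half-open [edge_i, edge_{i+1}), last regular bin closed above
        raw = np.searchsorted(edges, vv, side="right") - 1
        top = vv == edges[-1]
        raw[top] = len(edges) - 2
        if self.overflow_index is not None:
            over = vv > edges[-1]
            raw[over] = self.overflow_index
            if (vv < edges[0]).any():
                raise ValueError(f"value below range for kind {self.kind}")
        elif self.kind == "XHAT":
            # the two boundary bins are open-ended catch-alls for the
            # sparse extremes; +/-32.5 belong to the inner width-5 bins
            raw[vv < edges[0]] = 0
            raw[vv > edges[-1]] = len(edges) - 2
            raw[vv == -32.5] = 1
            raw[vv == 32.5] = len(edges) - 3
        else:
            if (raw < 0).any() or (vv > edges[-1]).any():
                raise ValueError(f"value out of range for kind {self.kind}")
        idx[ok] = raw
        return idx


def binning_for(kind: str, t_max: float | None = None) -> BinningScheme:
    """Construct the canonical binning scheme for a variable kind."""
    if kind == "XP":
        centers = np.arange(-10.0, 12.5, 5.0)
        edges = np.concatenate([centers - 2.5, [centers[-1] + 2.5]])
        return BinningScheme("XP", tuple(edges), tuple(centers))
    if kind == "XS":
        centers = np.arange(-20.0, 22.5, 5.0)
        edges = np.concatenate([centers - 2.5, [centers[-1] + 2.5]])
        return BinningScheme("XS", tuple(edges), tuple(centers) + (None,),
                             sentinel_index=len(centers))
    if kind == "XHAT":
        inner = np.arange(-30.0, 32.5, 5.0)
        edges = np.concatenate([[-40.0], inner - 2.5, [32.5, 40.0]])
        centers = (-36.25,) + tuple(inner) + (36.25,)
        return BinningScheme("XHAT", tuple(edges), centers)
    if kind in ("S", "M"):
        return BinningScheme(kind, (-0.5, 0.5, 1.5), (0.0, 1.0))
    if kind == "T":
        if t_max is None or t_max <= 0:
            raise ValueError("T binning requires a positive t_max")
        n = max(int(np.ceil((t_max - 0.2) / 0.2)), 1) + 1
        edges = np.arange(n + 1) * 0.2   # centers at 0.1 + 0.2k
        centers = tuple(edges[:-1] + 0.1) + (None,)
        return BinningScheme("T", tuple(edges), centers,
                             overflow_index=len(edges) - 1)
    raise ValueError(f"unknown variable kind: {kind}")


@dataclass
class HistogramDensity:
    """Plug-in pmf over one or several binning schemes."""

    binnings: tuple       # one BinningScheme per axis
    probs: np.ndarray     # ndim == len(binnings)
    n: int                # sample count behind the estimate

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != len(self.binnings):
            raise ValueError("probs dimensionality must match binnings")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    def marginal(self, axis: int) -> "HistogramDensity":
        keep = tuple(i for i in range(self.probs.ndim) if i != axis)
        return HistogramDensity(
            tuple(self.binnings[i] for i in (axis,)),
            self.probs.sum(axis=keep), self.n)


def histogram(values, binning: BinningScheme) -> HistogramDensity:
    """1-D maximum-likelihood histogram density."""
    idx = binning.assign(values)
    if idx.size == 0:
        raise ValueError("empty input")
    counts = np.bincount(idx, minlength=binning.n_bins).astype(float)
    return HistogramDensity((binning,), counts / idx.size, idx.size)


def joint_histogram(columns, binnings) -> HistogramDensity:
    """Joint pmf over 2 or 3 discretized columns.

    Marginalizing any axis reproduces the corresponding 1-D histogram
    exactly (same counts, same normalization).
    """
    if len(columns) != len(binnings):
        raise ValueError("one binning per column required")
    lengths = {len(np.atleast_1d(np.asarray(c, dtype=float))) for c in columns}
    if len(lengths) != 1:
        raise ValueError("columns must have equal length")
    n = lengths.pop()
    if n == 0:
        raise ValueError("empty input")
    idxs = [b.assign(c) for c, b in zip(columns, binnings)]
    shape = tuple(b.n_bins for b in binnings)
    flat = np.ravel_multi_index(idxs, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).astype(float)
    return HistogramDensity(tuple(binnings), counts.reshape(shape) / n, n)


def entropy(hist: HistogramDensity | np.ndarray) -> float:
    """Plug-in Shannon entropy in bits, with 0 log 0 := 0."""
    p = hist.probs if isinstance(hist, HistogramDensity) else np.asarray(hist)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
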