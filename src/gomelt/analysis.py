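"""Trajectory observables: Q_N, strand content, melting curves, landscapes.

The central order parameter is the fraction of native contacts Q_N: a
native pair (i, j) with reference distance r0 counts as *formed* when
its current distance is at most ``tolerance``·r0 (default 1.2).
Per-strand structure content is a contact-based proxy for per-strand
secondary structure: the fraction of a strand's native contacts
currently formed, normalised so the native conformation scores 1 for
every strand.  Melting curves carry block-averaged means and standard
errors; 2D free-energy surfaces are −kB·T·ln of a normalised histogram
over two collective variables, shifted so the occupied minimum is 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .go_model import KB, Conformation
from .rest2_engine import EffectiveTemperatureMap
from .structure_io import ContactMap

__all__ = [
    "MeltingCurve",
    "StrandProfile",
    "FreeEnergySurface",
    "fraction_native",
    "qn_series",
    "strand_content",
    "melting_curve",
    "histogram_observable",
    "free_energy_landscape",
    "block_stats",
]


def _pair_distances(coords: np.ndarray, cmap: ContactMap) -> np.ndarray:
    """Distances of the native pairs; coords is (..., n, 3)."""
    i = cmap.pairs[:, 0] - 1
    j = cmap.pairs[:, 1] - 1
    d = np.asarray(coords)[..., i, :] - np.asarray(coords)[..., j, :]
    return np.linalg.norm(d, axis=-1)


def fraction_native(conf: Conformation, cmap: ContactMap, tolerance: float = 1.2) -> float:
    """Fraction of native contacts formed in one conformation."""
    if len(cmap) == 0:
        raise ValueError("Q_N undefined for an empty contact map")
    if tolerance <= 1.0:
        raise ValueError("tolerance must exceed 1")
    r = _pair_distances(conf.coordinates, cmap)
    return float(np.mean(r <= tolerance * cmap.r0))


def qn_series(coords: np.ndarray, cmap: ContactMap, tolerance: float = 1.2) -> np.ndarray:
    """Vectorised Q_N over a stack of frames (frames, n, 3) → (frames,)."""
    if len(cmap) == 0:
        raise ValueError("Q_N undefined for an empty contact map")
    r = _pair_distances(coords, cmap)
    return np.mean(r <= tolerance * cmap.r0, axis=-1)


@dataclass(frozen=True)
class StrandProfile:
    """Per-strand native-contact content, native conformation = 1."""

    labels: list[str]
    content: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {lab: float(c) for lab, c in zip(self.labels, self.content)}


def strand_content(
    conf_or_coords: Conformation | np.ndarray,
    cmap: ContactMap,
    strand_ranges: dict[str, tuple[int, int]],
    tolerance: float = 1.2,
) -> StrandProfile | np.ndarray:
    """Per-strand fraction of native contacts currently formed.

    A contact belongs to strand k when at least one of its residues lies
    in the strand's range; the count of formed such contacts is divided
    by the strand's total native-contact count, so the native
    conformation scores 1 per strand.  Accepts a single Conformation
    (returns a StrandProfile) or a frame stack (returns an array of
    shape (frames, strands)).
    """
    coords = (
        conf_or_coords.coordinates
        if isinstance(conf_or_coords, Conformation)
        else np.asarray(conf_or_coords)
    )
    r = _pair_distances(coords, cmap)          # (..., m)
    formed = r <= tolerance * cmap.r0
    labels = list(strand_ranges)
    cols = []
    for lab in labels:
        a, b = strand_ranges[lab]
        member = (
            ((cmap.pairs[:, 0] >= a) & (cmap.pairs[:, 0] <= b))
            | ((cmap.pairs[:, 1] >= a) & (cmap.pairs[:, 1] <= b))
        )
        if not member.any():
            raise ValueError(f"strand {lab} has zero native contacts")
        cols.append(np.mean(formed[..., member], axis=-1))
    out = np.stack(cols, axis=-1)
    if isinstance(conf_or_coords, Conformation):
        return StrandProfile(labels=labels, content=out)
    return out


@dataclass(frozen=True)
class MeltingCurve:
    """⟨Q_N⟩ versus effective temperature with block-derived errors."""

    teff: np.ndarray
    qn_mean: np.ndarray
    qn_sem: np.ndarray
    n_blocks: int
    burn_in_fraction: float

    def __post_init__(self) -> None:
        t = np.asarray(self.teff, dtype=float)
        q = np.asarray(self.qn_mean, dtype=float)
        s = np.asarray(self.qn_sem, dtype=float)
        for name, arr in (("teff", t), ("qn_mean", q), ("qn_sem", s)):
            object.__setattr__(self, name, arr)
        if np.any(np.diff(t) <= 0):
            raise ValueError("teff must be strictly ascending")
        if np.any((q < -1e-12) | (q > 1 + 1e-12)) or np.any(s < 0):
            raise ValueError("qn_mean must lie in [0,1] and qn_sem be non-negative")


def block_stats(series: np.ndarray, burn_in_fraction: float, n_blocks: int) -> tuple[float, float]:
    """Block mean and SEM of one correlated series.

    Discards the leading ``burn_in_fraction``, splits the remainder into
    ``n_blocks`` contiguous equal blocks (truncating any remainder), and
    returns (mean of block means, SD of block means / √n_blocks).
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    x = np.asarray(series, dtype=float)
    x = x[int(round(len(x) * burn_in_fraction)):]
    if len(x) < n_blocks:
        raise ValueError("post-burn-in series shorter than n_blocks")
    per = len(x) // n_blocks
    blocks = x[: per * n_blocks].reshape(n_blocks, per).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=0) / np.sqrt(n_blocks))


def melting_curve(
    qn_by_rung: np.ndarray,
    teff_map: EffectiveTemperatureMap,
    burn_in_fraction: float = 0.4,
    n_blocks: int = 12,
) -> MeltingCurve:
    """Block-averaged melting curve from per-rung Q_N time series
    (shape (rungs, frames))."""
    qn_by_rung = np.asarray(qn_by_rung, dtype=float)
    means, sems = zip(*(block_stats(row, burn_in_fraction, n_blocks) for row in qn_by_rung))
    return MeltingCurve(
        teff=teff_map.teff,
        qn_mean=np.asarray(means),
        qn_sem=np.asarray(sems),
        n_blocks=n_blocks,
        burn_in_fraction=burn_in_fraction,
    )


def _block_means(series: np.ndarray, burn_in_fraction: float, n_blocks: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    x = x[int(round(len(x) * burn_in_fraction)):]
    if len(x) < n_blocks:
        raise ValueError("post-burn-in series shorter than n_blocks")
    per = len(x) // n_blocks
    return x[: per * n_blocks].reshape(n_blocks, per).mean(axis=1)


def melting_curve_pooled(
    qn_runs: list[np.ndarray],
    teff_map: EffectiveTemperatureMap,
    burn_in_fraction: float = 0.4,
    n_blocks: int = 12,
) -> MeltingCurve:
    """Melting curve pooled over independent replicate runs.

    Each replicate contributes ``n_blocks`` block means per rung after
    its own burn-in; the pooled mean and SEM are taken over all
    replicates' block means (R·n_blocks values per rung), so
    statistical error shrinks with both run length and replication.
    """
    if not qn_runs:
        raise ValueError("need at least one replicate")
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    n_rungs = np.asarray(qn_runs[0]).shape[0]
    means = np.empty(n_rungs)
    sems = np.empty(n_rungs)
    for r in range(n_rungs):
        blocks = np.concatenate([
            _block_means(np.asarray(run)[r], burn_in_fraction, n_blocks) for run in qn_runs
        ])
        means[r] = blocks.mean()
        sems[r] = blocks.std(ddof=0) / np.sqrt(len(blocks))
    return MeltingCurve(
        teff=teff_map.teff,
        qn_mean=means,
        qn_sem=sems,
        n_blocks=n_blocks * len(qn_runs),
        burn_in_fraction=burn_in_fraction,
    )


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray
    counts: np.ndarray      # counts or frequencies
    n_below: int
    n_above: int
    normalized: bool


def histogram_observable(values: np.ndarray, edges: np.ndarray, normalize: bool = False) -> Histogram:
    """Histogram with explicit overflow accounting (out-of-range values
    are counted, never silently dropped)."""
    edges = np.asarray(edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least 1 bin (2 edges)")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    v = np.asarray(values, dtype=float)
    n_below = int(np.sum(v < edges[0]))
    n_above = int(np.sum(v > edges[-1]))
    counts, _ = np.histogram(v, bins=edges)
    counts = counts.astype(float)
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return Histogram(edges=edges, counts=counts, n_below=n_below, n_above=n_above, normalized=normalize)


@dataclass(frozen=True)
class FreeEnergySurface:
    """F = −kB·T·ln P over two collective variables; occupied minimum at 0,
    empty bins masked (NaN in ``f_values``, True in ``mask``)."""

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    f_values: np.ndarray
    mask: np.ndarray
    temperature: float


def free_energy_landscape(
    cv1: np.ndarray,
    cv2: np.ndarray,
    temperature: float,
    edges: tuple[np.ndarray, np.ndarray],
    kB: float = KB,
) -> FreeEnergySurface:
    """2D free-energy surface from samples of two collective variables."""
    cv1 = np.asarray(cv1, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    if cv1.shape != cv2.shape:
        raise ValueError("cv1 and cv2 must have equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    e1, e2 = (np.asarray(e, dtype=float) for e in edges)
    counts, _, _ = np.histogram2d(cv1, cv2, bins=(e1, e2))
    total = counts.sum()
    if total == 0:
        raise ValueError("no samples fall inside the grid")
    p = counts / total
    mask = p == 0
    if np.sum(~mask) == 1:
        warnings.warn("all samples fall in a single bin; surface is one 0 with the rest masked")
    with np.errstate(divide="ignore"):
        f = -kB * temperature * np.log(np.where(mask, np.nan, p))
    f -= np.nanmin(f)
    f = np.where(mask, np.nan, f)
    return FreeEnergySurface(cv1_edges=e1, cv2_edges=e2, f_values=f, mask=mask, temperature=temperature)


def sheet_contact_counts(
    coords: np.ndarray,
    cmap: ContactMap,
    strand_ranges: dict[str, tuple[int, int]],
    sheet1: tuple[str, ...] = ("b1", "b2", "b3", "b6"),
    sheet2: tuple[str, ...] = ("b4", "b5", "b7", "b8"),
    tolerance: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Collective variables for the unfolding landscape: number of formed
    native contacts with both residues inside sheet 1 and inside sheet 2.

    The β-barrel's two sheets are the strand groups (β1, β2, β3, β6) and
    (β4, β5, β7, β8).  A contact belongs to a sheet when both of its
    residues lie in that sheet's strands.
    """
    def in_sheet(strands: tuple[str, ...]) -> np.ndarray:
        member1 = np.zeros(len(cmap), dtype=bool)
        member2 = np.zeros(len(cmap), dtype=bool)
        for lab in strands:
            a, b = strand_ranges[lab]
            member1 |= (cmap.pairs[:, 0] >= a) & (cmap.pairs[:, 0] <= b)
            member2 |= (cmap.pairs[:, 1] >= a) & (cmap.pairs[:, 1] <= b)
        return member1 & member2

    formed = _pair_distances(coords, cmap) <= tolerance * cmap.r0
    s1 = in_sheet(sheet1)
    s2 = in_sheet(sheet2)
    return formed[..., s1].sum(axis=-1), formed[..., s2].sum(axis=-1)
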