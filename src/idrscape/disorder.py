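"""Compositional disorder statistics, charge–hydropathy classification and
segmentation of per-residue disorder tracks into ordered/disordered regions.

The three analyses bundled here are the standard first-pass toolkit for
deciding whether a protein is intrinsically disordered:

* **Composition profiling** — the fractional difference in amino-acid
  composition of a query set relative to a reference set of ordered,
  globular proteins, ``D_X = (C_X - C_order) / C_order``, with percentile
  bootstrap confidence intervals from resampling residues within each set.
  Negative values mean depletion, positive enrichment; amino acids are
  displayed from most rigid to most flexible on the Vihinen scale.

* **Charge–hydropathy (Uversky) plot** — natively unfolded proteins
  separate from globular ones in the plane of mean net charge ⟨q⟩ vs mean
  normalized Kyte–Doolittle hydropathy ⟨H⟩; the boundary is the line
  ⟨q⟩ = 2.785·⟨H⟩ − 1.151 (a slightly different published variant,
  2.743/−1.109, is selectable).

* **Track segmentation** — per-residue disorder scores in [0, 1] (e.g. the
  output of PONDR-family predictors, consumed as input) are thresholded at
  0.5 by convention and turned into a partition of the sequence into
  alternating ordered/disordered regions, with short runs merged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .records import ProteinRecord
from .scales import (
    AMINO_ACIDS,
    CHARGE_PH7,
    KYTE_DOOLITTLE,
    VIHINEN_FLEXIBILITY,
    VIHINEN_ORDER,
    normalized,
)

#: Charge–hydropathy boundary coefficients (slope, intercept).
CH_BOUNDARIES: dict[str, tuple[float, float]] = {
    "methods": (2.785, -1.151),
    "figure": (2.743, -1.109),
}

Label = Literal["ordered", "disordered"]


# ---------------------------------------------------------------------------
# composition profiling


def composition(records: ProteinRecord | Iterable[ProteinRecord]) -> pd.Series:
    """Amino-acid frequency vector pooled over records by concatenation.

    Returns a Series indexed by the 20 canonical letters (alphabetical),
    summing to 1.
    """
    if isinstance(records, ProteinRecord):
        records = [records]
    pooled = "".join(r.sequence for r in records)
    if not pooled:
        raise ValueError("no residues")
    counts = np.array([pooled.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return pd.Series(counts / counts.sum(), index=list(AMINO_ACIDS), name="frequency")


@dataclass
class CompositionProfile:
    """Fractional-difference profile with bootstrap confidence intervals.

    ``table`` is indexed by amino acid in Vihinen order (rigid → flexible)
    with columns ``c_query``, ``c_ref``, ``d`` (= (C_X−C_order)/C_order),
    ``ci_low``, ``ci_high`` and ``undefined`` (True where C_order = 0 and
    the fractional difference does not exist).
    """

    table: pd.DataFrame
    n_boot: int
    ci_level: float

    @property
    def order(self) -> list[str]:
        return list(self.table.index)


def fractional_difference_profile(
    query: ProteinRecord | Iterable[ProteinRecord],
    reference: ProteinRecord | Iterable[ProteinRecord],
    n_boot: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> CompositionProfile:
    """Fractional difference in composition of ``query`` vs ``reference``.

    Both residue pools are resampled with replacement (equivalently, their
    letter counts are multinomial-resampled) ``n_boot`` times; the CI is the
    percentile interval of the bootstrap distribution of D_X. Letters absent
    from the reference pool are flagged ``undefined`` instead of being
    silently dropped.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    c_q = composition(query)
    c_r = composition(reference)
    rng = np.random.default_rng(seed)

    # residue-level bootstrap == multinomial resampling of the letter counts
    def _boot(freqs: pd.Series, n_res: int) -> np.ndarray:
        counts = rng.multinomial(n_res, freqs.to_numpy(), size=n_boot)
        return counts / n_res

    n_q = _pool_length(query)
    n_r = _pool_length(reference)
    bq = _boot(c_q, n_q)
    br = _boot(c_r, n_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_boot = (bq - br) / br
        d_point = (c_q.to_numpy() - c_r.to_numpy()) / c_r.to_numpy()
    alpha = 1.0 - ci_level
    lo = np.nanquantile(np.where(np.isfinite(d_boot), d_boot, np.nan), alpha / 2, axis=0)
    hi = np.nanquantile(np.where(np.isfinite(d_boot), d_boot, np.nan), 1 - alpha / 2, axis=0)
    undefined = c_r.to_numpy() == 0
    table = pd.DataFrame(
        {
            "c_query": c_q,
            "c_ref": c_r,
            "d": np.where(undefined, np.nan, d_point),
            "ci_low": np.where(undefined, np.nan, lo),
            "ci_high": np.where(undefined, np.nan, hi),
            "undefined": undefined,
        },
        index=list(AMINO_ACIDS),
    ).loc[VIHINEN_ORDER]
    return CompositionProfile(table=table, n_boot=n_boot, ci_level=ci_level)


def _pool_length(records: ProteinRecord | Iterable[ProteinRecord]) -> int:
    if isinstance(records, ProteinRecord):
        return len(records)
    return sum(len(r) for r in records)


# ---------------------------------------------------------------------------
# charge–hydropathy plot


@dataclass(frozen=True)
class CHPoint:
    """A protein's coordinates in the charge–hydropathy plane."""

    h: float
    q: float
    boundary_slope: float = CH_BOUNDARIES["methods"][0]
    boundary_intercept: float = CH_BOUNDARIES["methods"][1]

    @property
    def margin(self) -> float:
        """Signed distance above the boundary (positive = disordered side)."""
        return self.q - (self.boundary_slope * self.h + self.boundary_intercept)

    @property
    def label(self) -> Label:
        # a point exactly on the line is called disordered
        return "disordered" if self.margin >= 0 else "ordered"


def ch_point(
    record: ProteinRecord,
    boundary: str = "methods",
    window: int = 5,
) -> CHPoint:
    """Mean normalized hydropathy and mean net charge of a sequence.

    ⟨H⟩ is the Kyte–Doolittle hydropathy min–max normalized to [0, 1] and
    averaged over a sliding window of ``window`` residues (plain mean when
    the sequence is shorter); ⟨q⟩ is |Σ integer charges at pH 7| / length
    with K,R = +1 and D,E = −1, His neutral, termini excluded.
    """
    slope, intercept = CH_BOUNDARIES[boundary]
    kd = normalized(KYTE_DOOLITTLE)
    vals = np.array([kd[aa] for aa in record.sequence])
    if len(vals) >= window:
        smoothed = np.convolve(vals, np.ones(window) / window, mode="valid")
        h = float(smoothed.mean())
    else:
        h = float(vals.mean())
    q = abs(sum(CHARGE_PH7.get(aa, 0) for aa in record.sequence)) / len(record)
    return CHPoint(h=h, q=q, boundary_slope=slope, boundary_intercept=intercept)


def ch_classify(point: CHPoint) -> tuple[Label, float]:
    """Classify a CH-plane point; returns (label, signed margin)."""
    return point.label, point.margin


# ---------------------------------------------------------------------------
# score tracks and segmentation


@dataclass
class ScoreTrack:
    """Per-residue disorder scores in [0, 1], 1-based positions."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class RegionSet:
    """A partition of [1, L] into alternating ordered/disordered regions.

    ``regions`` is a sorted list of (start, end, label) with 1-based
    inclusive coordinates; adjacent regions carry different labels.
    """

    protein_id: str
    regions: list[tuple[int, int, Label]]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("empty region set")
        prev_end = 0
        prev_label = None
        for start, end, label in self.regions:
            if start != prev_end + 1 or end < start:
                raise ValueError(f"regions must tile [1, L]: bad interval ({start}, {end})")
            if label == prev_label:
                raise ValueError("adjacent regions must have different labels")
            prev_end, prev_label = end, label

    @property
    def length(self) -> int:
        return self.regions[-1][1]

    def implied_track(self) -> ScoreTrack:
        """Step track: 1.0 on disordered regions, 0.0 on ordered ones."""
        scores = np.zeros(self.length)
        for start, end, label in self.regions:
            if label == "disordered":
                scores[start - 1 : end] = 1.0
        return ScoreTrack(self.protein_id, scores)


def disorder_track_standin(record: ProteinRecord, window: int = 9) -> ScoreTrack:
    """Windowed flexibility-based disorder propensity.

    A deliberately simple stand-in track for pipelines without an external
    per-residue disorder prediction: the normalized Vihinen flexibility of
    each residue, averaged over a centered window (truncated at the edges).
    It is *not* equivalent to PONDR-family neural-network predictors, whose
    output tracks are the intended input of :func:`segment_regions`.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    flex = normalized(VIHINEN_FLEXIBILITY)
    vals = np.array([flex[aa] for aa in record.sequence])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(vals)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    scores = (csum[hi] - csum[lo]) / (hi - lo)
    return ScoreTrack(record.id, scores)


def segment_regions(
    track: ScoreTrack,
    threshold: float = 0.5,
    min_len: int = 4,
    sequence_length: int | None = None,
) -> RegionSet:
    """Partition a score track into ordered/disordered regions.

    Residues scoring strictly above ``threshold`` are disordered (the 0.5
    convention of PONDR-style plots). Runs shorter than ``min_len`` are
    merged into the label of the longer adjacent run (tie → the preceding
    run), shortest-first, until every surviving run has length ≥ min_len or
    a single region remains.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if sequence_length is not None and sequence_length != len(track):
        raise ValueError(
            f"track length {len(track)} does not match sequence length {sequence_length}"
        )
    labels = np.where(track.scores > threshold, 1, 0)  # 1 = disordered
    runs: list[list[int]] = []  # [label, length]
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([int(lab), 1])

    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        shortest = min(lengths)
        if shortest >= min_len:
            break
        i = lengths.index(shortest)  # leftmost among equals
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            # tie goes to the preceding run
            target = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[i][0] = runs[target][0]
        merged: list[list[int]] = []
        for lab, ln in runs:
            if merged and merged[-1][0] == lab:
                merged[-1][1] += ln
            else:
                merged.append([lab, ln])
        runs = merged

    regions: list[tuple[int, int, Label]] = []
    pos = 1
    for lab, ln in runs:
        regions.append((pos, pos + ln - 1, "disordered" if lab else "ordered"))
        pos += ln
    return RegionSet(track.protein_id, regions)
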