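"""Region-wise evolutionary distances under amino-acid substitution models.

The comparative question served here: within one protein family, do the
disordered regions of a reference protein diverge faster than its ordered
regions? The procedure is (1) align the homologs, (2) slice the alignment
into the sub-alignments spanned by each ordered/disordered region of the
reference, (3) compute the overall mean evolutionary distance of each
sub-alignment under three substitution models — the p-distance and
maximum-likelihood distances under the Dayhoff and JTT empirical matrices —
and (4) compare region means.

Distances are expressed in expected substitutions per site. For the
empirical models the rate matrix is built as Q_ij = S_ij·π_j from the
published symmetric exchangeabilities S and equilibrium frequencies π,
normalized so that −Σ_i π_i Q_ii = 1, and the pairwise distance is the t
maximizing Σ_sites log(π_a · P(t)_ab) with P(t) = exp(Qt). The matrix
exponential is evaluated by eigendecomposition of the π^(1/2)-symmetrized
generator, which is exact for these reversible models.
"""

from __future__ import annotations

import hashlib
import io as _io
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align as _bioalign
from Bio.Align import substitution_matrices
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .records import ProteinRecord

#: Amino-acid order used by the bundled empirical matrices (PAML convention).
AA_MODEL_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_MODEL_ORDER)}

#: sha256 of the bundled model data files; checked on load.
_DATA_CHECKSUMS = {
    "dayhoff.tsv": "53379bfa13f66f920a74622729ce1f667e06745879ab9c5261156bc97812c226",
    "jtt.tsv": "c3c0c2131103ca9ed1d794841ad3c1021c9680014627cadc0b62c7abdf52a1b4",
}

MODELS = ("p_distance", "dayhoff", "jtt")
DISTANCE_CAP = 10.0


# ---------------------------------------------------------------------------
# substitution models


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible empirical amino-acid substitution model."""

    name: str
    exchangeability: np.ndarray  # 20x20 symmetric, zero diagonal
    pi: np.ndarray  # equilibrium frequencies, sum 1

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator Q normalized to one expected substitution/site/unit t."""
        return _rate_matrix(self.name)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) via the symmetrized eigendecomposition."""
        w, left, right = _eig(self.name)
        return (right * np.exp(w * t)) @ left


@lru_cache(maxsize=None)
def load_model(name: str) -> SubstitutionModel:
    """Load a bundled empirical model ('dayhoff' or 'jtt')."""
    name = name.lower()
    if name not in ("dayhoff", "jtt"):
        raise ValueError(f"unknown empirical model {name!r}")
    fname = f"{name}.tsv"
    raw = resources.files("idrscape.data").joinpath(fname).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DATA_CHECKSUMS[fname]:
        raise RuntimeError(f"model data file {fname} failed its checksum")
    pi = None
    rows = []
    for line in raw.decode().splitlines():
        if line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "pi":
            pi = np.array([float(x) for x in parts[1:]])
        else:
            rows.append([float(x) for x in parts[1:]])
    S = np.array(rows)
    assert S.shape == (20, 20) and pi is not None
    pi = pi / pi.sum()
    return SubstitutionModel(name=name, exchangeability=S, pi=pi)


@lru_cache(maxsize=None)
def _rate_matrix(name: str) -> np.ndarray:
    m = load_model(name)
    Q = m.exchangeability * m.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(m.pi * np.diag(Q))
    return Q / mu


@lru_cache(maxsize=None)
def _eig(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = load_model(name)
    Q = _rate_matrix(name)
    sq = np.sqrt(m.pi)
    B = (sq[:, None] * Q) / sq[None, :]
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    right = V / sq[:, None]  # D^{-1/2} V
    left = V.T * sq[None, :]  # V^T D^{1/2}
    return w, left, right


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """A gapped multiple alignment; ungapping a row recovers its sequence."""

    records: list[tuple[str, str]]  # (id, aligned sequence with '-')
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must share one length")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def ungapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace("-", "")


def pairwise_align(
    a: ProteinRecord | tuple[str, str],
    b: ProteinRecord | tuple[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two
    sequences; a gap of length L costs ``gap_open + (L-1)·gap_extend``.
    """
    ia, sa = (a.id, a.sequence) if isinstance(a, ProteinRecord) else a
    ib, sb = (b.id, b.sequence) if isinstance(b, ProteinRecord) else b
    aligner = _bioalign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    result = aligner.align(sa, sb)
    best = result[0]
    ga, gb = str(best[0]), str(best[1])
    return Alignment(records=[(ia, ga), (ib, gb)], score=float(result.score))


def center_star_msa(
    seqs: Sequence[ProteinRecord | tuple[str, str]],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Center-star progressive alignment ("once a gap, always a gap").

    The center is the sequence maximizing summed pairwise alignment scores;
    the remaining sequences are merged one by one onto the growing master
    alignment through their pairwise alignment with the center.
    """
    pairs = [(r.id, r.sequence) if isinstance(r, ProteinRecord) else tuple(r) for r in seqs]
    if len(pairs) < 2:
        raise ValueError("need at least two sequences")
    n = len(pairs)
    scores = np.zeros((n, n))
    alns: dict[tuple[int, int], Alignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(pairs[i], pairs[j], matrix, gap_open, gap_extend)
            alns[(i, j)] = aln
            scores[i, j] = scores[j, i] = aln.score
    center = int(np.argmax(scores.sum(axis=1)))

    master = pairs[center][1]  # center row of the growing MSA
    rows: list[tuple[int, str]] = [(center, master)]
    for j in range(n):
        if j == center:
            continue
        key = (center, j) if center < j else (j, center)
        aln = alns[key]
        c_aln = aln.row(pairs[center][0]) if center < j else aln.row(pairs[center][0])
        o_aln = aln.row(pairs[j][0])
        master, rows, new_row = _merge_onto_master(master, rows, c_aln, o_aln)
        rows.append((j, new_row))
    id_by_index = {idx: pairs[idx][0] for idx in range(n)}
    ordered = sorted(rows, key=lambda r: r[0])
    return Alignment(records=[(id_by_index[i], s) for i, s in ordered])


def _merge_onto_master(
    master: str,
    rows: list[tuple[int, str]],
    center_aln: str,
    other_aln: str,
) -> tuple[str, list[tuple[int, str]], str]:
    """Merge one pairwise (center, other) alignment into the master MSA."""
    mi = ci = 0
    new_master: list[str] = []
    new_other: list[str] = []
    inserts_master: list[int] = []  # master positions where a column is inserted
    while mi < len(master) or ci < len(center_aln):
        m_ch = master[mi] if mi < len(master) else None
        c_ch = center_aln[ci] if ci < len(center_aln) else None
        if m_ch == "-" and (c_ch is None or c_ch != "-"):
            # master has an old gap column the pairwise alignment lacks
            new_master.append("-")
            new_other.append("-")
            mi += 1
        elif c_ch == "-" and (m_ch is None or m_ch != "-"):
            # pairwise alignment inserts a gap into the center
            new_master.append("-")
            new_other.append(other_aln[ci])
            inserts_master.append(mi)
            ci += 1
        else:
            new_master.append(m_ch if m_ch is not None else "-")
            new_other.append(other_aln[ci] if c_ch is not None else "-")
            mi += 1
            ci += 1
    # propagate the newly inserted columns into the existing rows
    patched: list[tuple[int, str]] = []
    for idx, row in rows:
        out: list[str] = []
        ins = 0
        for pos in range(len(row) + 1):
            while ins < len(inserts_master) and inserts_master[ins] == pos:
                out.append("-")
                ins += 1
            if pos < len(row):
                out.append(row[pos])
        patched.append((idx, "".join(out)))
    return "".join(new_master), patched, "".join(new_other)


def region_subalignment(msa: Alignment, reference_id: str, start: int, end: int) -> Alignment:
    """Columns of the MSA spanned by reference residues [start, end]
    (1-based inclusive), including any gap columns interior to the block.
    """
    ref = msa.row(reference_id)
    ref_len = len(ref) - ref.count("-")
    if not (1 <= start <= end <= ref_len):
        raise ValueError(f"region [{start}, {end}] out of range for reference of length {ref_len}")
    cols = []
    res = 0
    for col, ch in enumerate(ref):
        if ch != "-":
            res += 1
            if res == start:
                cols.append(col)
            if res == end:
                cols.append(col)
                break
    lo, hi = cols[0], cols[-1]
    return Alignment(records=[(i, s[lo : hi + 1]) for i, s in msa.records])


# ---------------------------------------------------------------------------
# distances


@dataclass(frozen=True)
class PairDistance:
    distance: float  # substitutions/site; nan if undefined
    sites: int
    capped: bool

    @property
    def defined(self) -> bool:
        return np.isfinite(self.distance)


def pair_distance(
    a: str,
    b: str,
    model: str = "p_distance",
    cap: float = DISTANCE_CAP,
) -> PairDistance:
    """Distance between two aligned rows; gapped sites excluded pairwise."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    ia, ib = [], []
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            ia.append(_AA_INDEX[x])
            ib.append(_AA_INDEX[y])
    sites = len(ia)
    if sites == 0:
        return PairDistance(distance=float("nan"), sites=0, capped=False)
    ia_arr = np.array(ia)
    ib_arr = np.array(ib)
    diffs = int(np.sum(ia_arr != ib_arr))
    if model == "p_distance":
        return PairDistance(distance=diffs / sites, sites=sites, capped=False)
    m = load_model(model)
    if diffs == 0:
        return PairDistance(distance=0.0, sites=sites, capped=False)
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia_arr, ib_arr), 1.0)
    log_pi = np.log(m.pi)

    def neg_loglik(t: float) -> float:
        P = m.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(np.maximum(P, 1e-300)))
        return -float(ll.sum())

    res = minimize_scalar(neg_loglik, bounds=(1e-9, cap), method="bounded",
                          options={"xatol": 1e-8})
    t_hat = float(res.x)
    if t_hat >= cap - 1e-3:
        return PairDistance(distance=cap, sites=sites, capped=True)
    return PairDistance(distance=t_hat, sites=sites, capped=False)


@dataclass
class DistanceEstimate:
    """Pairwise distance matrix and overall mean for one alignment/model."""

    model: str
    matrix: pd.DataFrame  # symmetric, zero diagonal; nan where undefined
    sites: pd.DataFrame
    capped_pairs: list[tuple[str, str]]
    undefined_pairs: list[tuple[str, str]]

    @property
    def mean(self) -> float:
        """Arithmetic mean over defined, uncapped unordered pairs."""
        ids = list(self.matrix.index)
        excluded = set(map(frozenset, self.capped_pairs)) | set(
            map(frozenset, self.undefined_pairs)
        )
        vals = [
            self.matrix.iloc[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if frozenset((ids[i], ids[j])) not in excluded
        ]
        if not vals:
            raise ValueError("no defined pairs to average")
        return float(np.mean(vals))


def mean_region_distance(
    aln: Alignment,
    model: str = "p_distance",
    complete_deletion: bool = False,
    cap: float = DISTANCE_CAP,
) -> DistanceEstimate:
    """Overall mean evolutionary distance over all unordered row pairs.

    With ``complete_deletion`` every column containing a gap in any row is
    removed before any pair is compared (MEGA-style complete deletion);
    the default excludes gapped sites per pair (pairwise deletion).
    """
    if len(aln.records) < 2:
        raise ValueError("need at least two rows")
    records = aln.records
    if complete_deletion:
        keep = [
            c for c in range(aln.length) if all(s[c] != "-" for _, s in records)
        ]
        records = [(i, "".join(s[c] for c in keep)) for i, s in records]
    ids = [i for i, _ in records]
    n = len(ids)
    mat = np.zeros((n, n))
    sit = np.zeros((n, n), dtype=int)
    capped, undefined = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pd_ij = pair_distance(records[i][1], records[j][1], model, cap)
            mat[i, j] = mat[j, i] = pd_ij.distance
            sit[i, j] = sit[j, i] = pd_ij.sites
            if pd_ij.capped:
                capped.append((ids[i], ids[j]))
            if not pd_ij.defined:
                undefined.append((ids[i], ids[j]))
    if capped or undefined:
        warnings.warn(
            f"{len(capped)} saturated and {len(undefined)} undefined pairs "
            "excluded from the mean distance",
            stacklevel=2,
        )
    est = DistanceEstimate(
        model=model,
        matrix=pd.DataFrame(mat, index=ids, columns=ids),
        sites=pd.DataFrame(sit, index=ids, columns=ids),
        capped_pairs=capped,
        undefined_pairs=undefined,
    )
    if len(capped) + len(undefined) == (n * (n - 1)) // 2:
        raise ValueError("all pairs undefined or saturated")
    return est


# ---------------------------------------------------------------------------
# trees


def nj_tree(est: DistanceEstimate) -> str:
    """Neighbor-joining tree (newick) from a distance estimate.

    Negative branch lengths are clamped to zero. Saturated or undefined
    entries make the matrix unusable and raise.
    """
    ids = list(est.matrix.index)
    if len(ids) < 3:
        raise ValueError("need at least three taxa")
    if est.capped_pairs or est.undefined_pairs:
        raise ValueError("distance matrix contains capped or undefined entries")
    dm = DistanceMatrix(est.matrix.to_numpy(), ids)
    tree = _skbio_nj(dm, neg_as_zero=True)
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
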