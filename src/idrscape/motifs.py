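"""Motif-level physicochemical metrics and Cdk phosphosite organization.

Short conserved motifs inside disordered regions are characterized by
their grand average of hydropathy (GRAVY), local isoelectric point and
charged-residue content; Cdk phospho-acceptor sites are found by consensus
scanning ([S/T]-P minimal, [S/T]-P-x-[K/R] full), assigned to motifs, and
ranked into a "phosphorylation rhythm" by externally supplied
kinase-preference scores (higher score = earlier phosphorylated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .records import ProteinRecord
from .scales import (
    KYTE_DOOLITTLE,
    PKA_CTERMINAL,
    PKA_NEGATIVE_SIDE,
    PKA_NTERMINAL,
    PKA_NTERMINAL_DEFAULT,
    PKA_POSITIVE_SIDE,
)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: Kyte–Doolittle sum / length."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(KYTE_DOOLITTLE[aa] for aa in seq) / len(seq)


def net_charge(seq: str, ph: float, include_termini: bool = True) -> float:
    """Net charge at a given pH under the Bjellqvist/ProtParam pKa set.

    Positive groups contribute 1/(1+10^(pH−pKa)), negative ones
    −1/(1+10^(pKa−pH)).
    """
    if not seq:
        raise ValueError("empty sequence")
    pos_pkas = [PKA_POSITIVE_SIDE[aa] for aa in seq if aa in PKA_POSITIVE_SIDE]
    neg_pkas = [PKA_NEGATIVE_SIDE[aa] for aa in seq if aa in PKA_NEGATIVE_SIDE]
    if include_termini:
        pos_pkas.append(PKA_NTERMINAL.get(seq[0], PKA_NTERMINAL_DEFAULT))
        neg_pkas.append(PKA_CTERMINAL)
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - pka)) for pka in pos_pkas)
    charge -= sum(1.0 / (1.0 + 10.0 ** (pka - ph)) for pka in neg_pkas)
    return charge


def isoelectric_point(
    seq: str,
    include_termini: bool = True,
    tol: float = 1e-4,
) -> tuple[float, bool]:
    """pH of zero net charge, solved by bisection on [0, 14].

    Bisection narrows the bracket to a pH width of ``tol``/10 (so the
    returned pI is positionally accurate even where the charge curve is
    shallow) and the residual charge there satisfies |charge| < ``tol`` on
    any realistic sequence. Returns (pI, at_bound); ``at_bound`` is True
    when the charge curve has no zero crossing in [0, 14] (e.g. no
    ionizable groups at all) and the nearer bound is returned instead.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(seq, lo, include_termini), net_charge(seq, hi, include_termini)
    if c_lo <= 0:
        return lo, True
    if c_hi >= 0:
        return hi, True
    while hi - lo > tol / 10.0:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, include_termini) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0, False


def charge_content(seq: str, include_his: bool = False) -> tuple[float, float]:
    """(% positively, % negatively) charged residues over the length.

    Positive counts K and R (H included only on request — conventions
    differ); negative counts D and E.
    """
    if not seq:
        raise ValueError("empty sequence")
    pos_set = "KRH" if include_his else "KR"
    pos = sum(seq.count(aa) for aa in pos_set)
    neg = seq.count("D") + seq.count("E")
    return 100.0 * pos / len(seq), 100.0 * neg / len(seq)


# ---------------------------------------------------------------------------
# motifs and phosphosites


@dataclass(frozen=True)
class Motif:
    """A named 1-based inclusive interval on a protein sequence."""

    protein_id: str
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad motif interval [{self.start}, {self.end}]")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def slice(self, sequence: str) -> str:
        if self.end > len(sequence):
            raise ValueError(f"motif {self.name} exceeds sequence length")
        return sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class PhosphoSite:
    """A phospho-acceptor residue with an optional kinase-preference score."""

    protein_id: str
    position: int  # 1-based
    residue: str  # S, T or Y
    consensus: Literal["minimal", "full", "none"] = "none"
    score: float | None = None
    site_index: int | None = None


def scan_cdk_sites(
    record: ProteinRecord, mode: Literal["minimal", "full"] = "minimal"
) -> list[PhosphoSite]:
    """Cdk consensus scan: minimal = S/T immediately followed by P;
    full = [S/T]-P-x-[K/R]. Positions 1-based, ascending.
    """
    seq = record.sequence
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in "ST" and seq[i + 1] == "P":
            if mode == "full":
                if i + 3 >= len(seq) or seq[i + 3] not in "KR":
                    continue
            sites.append(
                PhosphoSite(record.id, i + 1, seq[i], consensus=mode)
            )
    return sites


def assign_sites_to_motifs(
    sites: Sequence[PhosphoSite], motifs: Sequence[Motif]
) -> dict[str, list[PhosphoSite]]:
    """Partition sites into per-motif buckets plus an ``inter-motif`` bucket.

    Motifs must be non-overlapping; every site lands in exactly one bucket.
    """
    ordered = sorted(motifs, key=lambda m: m.start)
    for m1, m2 in zip(ordered, ordered[1:]):
        if m2.start <= m1.end:
            raise ValueError(f"motifs {m1.name} and {m2.name} overlap")
    buckets: dict[str, list[PhosphoSite]] = {m.name: [] for m in ordered}
    buckets["inter-motif"] = []
    for site in sorted(sites, key=lambda s: s.position):
        for m in ordered:
            if m.contains(site.position):
                buckets[m.name].append(site)
                break
        else:
            buckets["inter-motif"].append(site)
    return buckets


@dataclass
class RhythmRanking:
    """Sites ordered by inferred phosphorylation timing (rank 1 earliest)."""

    sites: list[PhosphoSite]

    @property
    def ranks(self) -> dict[int, int]:
        """Map position → rank."""
        return {s.position: r for r, s in enumerate(self.sites, start=1)}


def rank_phospho_rhythm(sites: Sequence[PhosphoSite]) -> RhythmRanking:
    """Rank sites by descending kinase-preference score (ties by ascending
    position): the highest-scoring site is inferred to be phosphorylated
    earliest.
    """
    for s in sites:
        if s.score is None or not np.isfinite(s.score):
            raise ValueError(f"site at position {s.position} has no finite score")
    ordered = sorted(sites, key=lambda s: (-s.score, s.position))
    return RhythmRanking(sites=list(ordered))
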