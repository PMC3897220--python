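"""Seeded generators for every input class the pipeline consumes.

These generators encode the statistical structure the analyses assume —
disordered-like vs globular-like residue composition, homolog families
evolved with region-specific substitution rates on a star phylogeny,
interactomes with planted shell structure, phosphosite score tables with a
planted temporal order, and log-linear gel-filtration standards — so that
every stage is testable without any external download. They emulate the
*structure* of real inputs, not their full realism (no indels, no rate
heterogeneity beyond region multipliers, no curated-database noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .disorder import RegionSet
from .evolution import AA_MODEL_ORDER, load_model
from .network import InteractionEdge, ShellAssignment
from .records import ProteinRecord
from .scales import AMINO_ACIDS


def _globular_composition() -> dict[str, float]:
    # JTT equilibrium frequencies: a published average over globular,
    # mostly ordered protein families — a reasonable ordered background.
    m = load_model("jtt")
    return {aa: float(p) for aa, p in zip(AA_MODEL_ORDER, m.pi)}


def _disordered_composition() -> dict[str, float]:
    # Tilt the globular background the way disordered proteomes are tilted:
    # deplete the order-promoting C, W, F, Y, V, I and enrich the
    # disorder-promoting Q, S, P, E (plus mildly T and R).
    comp = _globular_composition()
    for aa in "CWFYVI":
        comp[aa] *= 0.35
    for aa in "QSPE":
        comp[aa] *= 1.9
    for aa in "TR":
        comp[aa] *= 1.3
    total = sum(comp.values())
    return {aa: v / total for aa, v in comp.items()}


def composition_preset(name: str) -> dict[str, float]:
    """Bundled composition presets: ``globular`` and ``disordered``."""
    if name == "globular":
        return _globular_composition()
    if name == "disordered":
        return _disordered_composition()
    raise ValueError(f"unknown composition preset {name!r}")


def sample_sequence(
    composition: dict[str, float],
    length: int,
    seed: int | np.random.Generator | None = None,
    record_id: str = "synthetic",
) -> ProteinRecord:
    """Sample an i.i.d. sequence from a 20-letter composition."""
    if length < 1:
        raise ValueError("length must be >= 1")
    letters = sorted(composition)
    probs = np.array([composition[aa] for aa in letters], dtype=float)
    if set(letters) != set(AMINO_ACIDS) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
        raise ValueError("composition must assign non-negative mass summing to 1 over the 20 letters")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = "".join(rng.choice(list(letters), size=length, p=probs))
    return ProteinRecord(record_id, seq, "synthetic i.i.d. sequence")


# ---------------------------------------------------------------------------
# homolog families with region-specific rates


@dataclass
class FamilyConfig:
    """Star-phylogeny family with per-region rate multipliers.

    ``branch_length`` is in expected substitutions/site at the ordered-
    region rate; a region with multiplier k evolves along each branch for
    an effective length k·branch_length. No indels are introduced, so the
    leaves are returned already aligned (the true, gap-free alignment).
    """

    root_length: int = 400
    n_leaves: int = 8
    branch_length: float = 0.3
    model: str = "jtt"
    regions: list[tuple[int, int, str]] = field(default_factory=list)
    multipliers: dict[str, float] = field(
        default_factory=lambda: {"ordered": 1.0, "disordered": 3.0}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.regions:
            half = self.root_length // 2
            self.regions = [
                (1, half, "ordered"),
                (half + 1, self.root_length, "disordered"),
            ]
        if self.regions[-1][1] != self.root_length or self.regions[0][0] != 1:
            raise ValueError("region layout must cover [1, root_length]")
        if self.branch_length < 0:
            raise ValueError("branch lengths must be >= 0")
        for label, k in self.multipliers.items():
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"multiplier for {label!r} must be finite and >= 0")


@dataclass
class SimulatedFamily:
    alignment: "Alignment"
    regions: RegionSet
    root: str


def simulate_family(cfg: FamilyConfig, root: str | None = None) -> SimulatedFamily:
    """Evolve a family on a star phylogeny with region-specific rates."""
    from .evolution import Alignment  # local import to avoid a cycle

    model = load_model(cfg.model)
    rng = np.random.default_rng(cfg.seed)
    aa = np.array(list(AA_MODEL_ORDER))
    if root is None:
        root_idx = rng.choice(20, size=cfg.root_length, p=model.pi)
    else:
        if len(root) != cfg.root_length:
            raise ValueError("root length does not match config")
        lookup = {c: i for i, c in enumerate(AA_MODEL_ORDER)}
        root_idx = np.array([lookup[c] for c in root])

    site_mult = np.empty(cfg.root_length)
    for start, end, label in cfg.regions:
        site_mult[start - 1 : end] = cfg.multipliers[label]

    leaves = []
    for leaf in range(cfg.n_leaves):
        child = root_idx.copy()
        for k in np.unique(site_mult):
            t = cfg.branch_length * float(k)
            sites = np.where(site_mult == k)[0]
            if t == 0 or len(sites) == 0:
                continue
            P = model.transition_matrix(t)
            P = np.maximum(P, 0)
            P /= P.sum(axis=1, keepdims=True)
            for s in sites:
                child[s] = rng.choice(20, p=P[root_idx[s]])
        leaves.append((f"leaf{leaf + 1}", "".join(aa[child])))

    region_set = RegionSet("leaf1", [(s, e, lab) for s, e, lab in cfg.regions])
    return SimulatedFamily(
        alignment=Alignment(records=leaves),
        regions=region_set,
        root="".join(aa[root_idx]),
    )


# ---------------------------------------------------------------------------
# interactomes with planted shells


@dataclass
class NetConfig:
    """Planted shell structure around one focus protein."""

    n_level1: int = 5
    n_level2: int = 8
    n_level3: int = 6
    n_outer: int = 10
    spurious_edge_prob: float = 0.0
    focus: str = "FOCUS"
    seed: int | None = None

    def __post_init__(self) -> None:
        for n in (self.n_level1, self.n_level2, self.n_level3, self.n_outer):
            if n < 0:
                raise ValueError("shell counts must be >= 0")
        if not (0.0 <= self.spurious_edge_prob <= 1.0):
            raise ValueError("spurious edge probability must be in [0, 1]")


def synth_interactome(cfg: NetConfig) -> tuple[list[InteractionEdge], ShellAssignment]:
    """Edge table with planted shells plus the generating truth.

    Physical edges: focus↔level-1, level-2↔level-1, level-3↔level-2.
    Genetic edges: focus↔levels 2, 3 and outer. Spurious physical edges
    between random non-focus pairs are added with the stated probability
    (they may promote planted outer/level-3 proteins, so the returned truth
    is exact only at zero noise).
    """
    rng = np.random.default_rng(cfg.seed)
    l1 = [f"P1_{i}" for i in range(cfg.n_level1)]
    l2 = [f"P2_{i}" for i in range(cfg.n_level2)]
    l3 = [f"P3_{i}" for i in range(cfg.n_level3)]
    outer = [f"OUT_{i}" for i in range(cfg.n_outer)]
    edges: list[InteractionEdge] = []
    for p in l1:
        edges.append(InteractionEdge(cfg.focus, p, "physical", "planted"))
    for i, p in enumerate(l2):
        edges.append(InteractionEdge(cfg.focus, p, "genetic", "planted"))
        if l1:
            edges.append(InteractionEdge(p, l1[i % len(l1)], "physical", "planted"))
    for i, p in enumerate(l3):
        edges.append(InteractionEdge(cfg.focus, p, "genetic", "planted"))
        if l2:
            edges.append(InteractionEdge(p, l2[i % len(l2)], "physical", "planted"))
    for p in outer:
        edges.append(InteractionEdge(cfg.focus, p, "genetic", "planted"))
    if cfg.spurious_edge_prob > 0:
        others = l1 + l2 + l3 + outer
        for i in range(len(others)):
            for j in range(i + 1, len(others)):
                if rng.random() < cfg.spurious_edge_prob:
                    edges.append(
                        InteractionEdge(others[i], others[j], "physical", "spurious")
                    )
    truth = ShellAssignment(
        focus=cfg.focus,
        levels={
            **{p: "1" for p in l1},
            **{p: "2" for p in l2},
            **{p: "3" for p in l3},
            **{p: "outer" for p in outer},
        },
    )
    return edges, truth


# ---------------------------------------------------------------------------
# phosphosite score tables and gel-filtration standards


def synth_phospho_table(
    positions: list[int],
    planted_order: list[int],
    noise_sd: float = 0.0,
    seed: int | None = None,
    protein_id: str = "synthetic",
) -> pd.DataFrame:
    """Score table with a planted phosphorylation rhythm.

    ``planted_order`` lists the positions from earliest to latest; scores
    are a descending arithmetic sequence in that order plus Gaussian noise.
    """
    if not positions:
        raise ValueError("need at least one site")
    if sorted(planted_order) != sorted(positions):
        raise ValueError("planted_order must be a permutation of positions")
    rng = np.random.default_rng(seed)
    base = {pos: float(len(positions) - i) for i, pos in enumerate(planted_order)}
    rows = [
        {
            "protein_id": protein_id,
            "pos": pos,
            "residue": "S",
            "score": base[pos] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
            "site_index": i + 1,
        }
        for i, pos in enumerate(sorted(positions))
    ]
    return pd.DataFrame(rows)


def rhythm_recovery(
    positions: list[int],
    planted_order: list[int],
    noise_sd: float,
    seed: int | None = None,
) -> float:
    """Spearman correlation between a planted rhythm and its recovery.

    Generates a noisy score table, re-ranks it, and reports how well the
    planted temporal order survives the noise (1 = perfect recovery).
    """
    from scipy.stats import spearmanr

    from .motifs import PhosphoSite, rank_phospho_rhythm

    table = synth_phospho_table(positions, planted_order, noise_sd, seed)
    sites = [
        PhosphoSite(str(r.protein_id), int(r.pos), str(r.residue), score=float(r.score))
        for r in table.itertuples()
    ]
    recovered = [s.position for s in rank_phospho_rhythm(sites).sites]
    planted_rank = {pos: i for i, pos in enumerate(planted_order)}
    rho, _ = spearmanr(
        [planted_rank[p] for p in recovered], list(range(len(recovered)))
    )
    return float(rho)


#: Masses (Da) of the five classic globular column standards.
PRINTED_STANDARDS = {
    "BSA": 66_000.0,
    "ovalbumin": 43_000.0,
    "chymotrypsin": 23_000.0,
    "myoglobin": 17_000.0,
    "cytochrome_c": 13_600.0,
}


def synth_gf_standards(
    slope: float = -0.1,
    intercept: float = 6.0,
    elutions: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gel-filtration standards on a log-linear mass/elution law.

    Masses are 10^(slope·elution + intercept), optionally with
    multiplicative log-normal noise (``noise_sd`` in log10 units).
    """
    if elutions is None:
        elutions = [8.0, 10.0, 12.0, 14.0, 16.0]
    if len(elutions) < 2:
        raise ValueError("need at least two elution values")
    rng = np.random.default_rng(seed)
    rows = []
    for i, e in enumerate(elutions):
        log_mass = slope * e + intercept
        if noise_sd > 0:
            log_mass += rng.normal(0.0, noise_sd)
        rows.append({"name": f"std{i + 1}", "mass_da": 10.0**log_mass, "elution": e})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# a deterministic disordered-hub stand-in sequence


def whi5_like_sequence(seed: int = 2013) -> ProteinRecord:
    """A synthetic stand-in for a disordered G1/S-inhibitor hub sequence.

    The real protein's sequence is not bundled; this deterministic
    295-residue surrogate reproduces its *documented architecture* so the
    scanning/assignment machinery can be exercised end to end: twelve
    minimal Cdk ([S/T]-P) sites, including T143, S154, S156, S161 (motif 1,
    residues 136–162), T215 (between motifs 2 and 3) and S262 (motif 3,
    residues 245–267); six further sites in the variable N-terminal region;
    no phospho-acceptor consensus inside motif 2 (173–209); and an overall
    disordered-like composition. It is synthetic and must not be mistaken
    for the natural sequence.
    """
    rng = np.random.default_rng(seed)
    base = list(sample_sequence(composition_preset("disordered"), 295, rng).sequence)
    planted = {33: "S", 41: "T", 55: "S", 72: "S", 88: "T", 101: "S",
               143: "T", 154: "S", 156: "S", 161: "S", 215: "T", 262: "S"}
    for pos, res in planted.items():
        base[pos - 1] = res
        base[pos] = "P"
    # scrub accidental S/T-P dinucleotides elsewhere
    for i in range(len(base) - 1):
        if base[i] in "ST" and base[i + 1] == "P" and (i + 1) not in planted:
            base[i + 1] = "A"
    seq = "".join(base)
    rec = ProteinRecord("WHI5_SYNTHETIC", seq, "synthetic disordered-hub stand-in")
    return rec


def whi5_like_motifs(protein_id: str = "WHI5_SYNTHETIC") -> list:
    """The documented three-motif layout on the stand-in coordinates."""
    from .motifs import Motif

    return [
        Motif(protein_id, "motif1", 136, 162),
        Motif(protein_id, "motif2", 173, 209),
        Motif(protein_id, "motif3", 245, 267),
    ]
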