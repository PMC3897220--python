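"""Tab-separated readers/writers for the pipeline's table dialects.

All tables are plain TSV with a header row. Columns:

* score tracks      — ``protein_id, pos, score`` (pos 1-based)
* region sets       — ``protein_id, start, end, label``
* motifs            — ``protein_id, name, start, end``
* phosphosites      — ``protein_id, pos, residue, score, site_index``
* interaction edges — ``a, b, etype, source`` (etype physical|genetic)
* annotations       — ``term, protein_id``
* GF standards      — ``name, mass_da, elution``
* classes           — ``protein_id, function``
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .disorder import RegionSet, ScoreTrack
from .motifs import Motif, PhosphoSite
from .network import InteractionEdge


def read_score_track(path: str | Path, protein_id: str | None = None) -> ScoreTrack:
    df = pd.read_csv(path, sep="\t")
    if protein_id is not None:
        df = df[df["protein_id"] == protein_id]
    ids = df["protein_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one protein in track file, found {len(ids)}")
    df = df.sort_values("pos")
    if list(df["pos"]) != list(range(1, len(df) + 1)):
        raise ValueError("track positions must be 1..L without gaps")
    return ScoreTrack(str(ids[0]), df["score"].to_numpy())


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_id": track.protein_id,
            "pos": np.arange(1, len(track) + 1),
            "score": track.scores,
        }
    ).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path, protein_id: str | None = None) -> RegionSet:
    df = pd.read_csv(path, sep="\t")
    if protein_id is not None:
        df = df[df["protein_id"] == protein_id]
    ids = df["protein_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one protein in regions file, found {len(ids)}")
    df = df.sort_values("start")
    regions = [(int(r.start), int(r.end), str(r.label)) for r in df.itertuples()]
    return RegionSet(str(ids[0]), regions)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"protein_id": regions.protein_id, "start": s, "end": e, "label": lab}
            for s, e, lab in regions.regions
        ]
    ).to_csv(path, sep="\t", index=False)


def read_motifs(path: str | Path) -> list[Motif]:
    df = pd.read_csv(path, sep="\t")
    return [
        Motif(str(r.protein_id), str(r.name), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_phosphosites(path: str | Path) -> list[PhosphoSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for r in df.itertuples():
        site_index = None
        if "site_index" in df.columns and not pd.isna(r.site_index):
            site_index = int(r.site_index)
        sites.append(
            PhosphoSite(
                protein_id=str(r.protein_id),
                position=int(r.pos),
                residue=str(r.residue),
                score=float(r.score) if not pd.isna(r.score) else None,
                site_index=site_index,
            )
        )
    return sites


def read_edges(path: str | Path) -> list[InteractionEdge]:
    df = pd.read_csv(path, sep="\t")
    src = df["source"] if "source" in df.columns else [""] * len(df)
    return [
        InteractionEdge(str(a), str(b), str(t), str(s))
        for a, b, t, s in zip(df["a"], df["b"], df["etype"], src)
    ]


def write_edges(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    pd.DataFrame(
        [{"a": e.a, "b": e.b, "etype": e.etype, "source": e.source} for e in edges]
    ).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.term), set()).add(str(r.protein_id))
    return out


def read_standards(path: str | Path) -> list[tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(m), float(e)) for m, e in zip(df["mass_da"], df["elution"])]


def read_classes(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.protein_id): str(r.function) for r in df.itertuples()}
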