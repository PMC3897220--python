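"""Orchestration of the comparative workflows into one reproducible run.

Two workflows are wired together from a single config: the
disorder/evolution track (composition profile, CH classification,
segmentation, region-wise evolutionary distances, motif/phosphosite
organization, hydrodynamics) and the interactome track (shell
decomposition plus term enrichment). Every run emits a JSON report holding
the resolved parameters, sha256 checksums of the inputs and the headline
numbers of each stage; identical config and inputs give identical reports
apart from the single timestamp field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import disorder, hydro, io, motifs, network, synthetic
from .evolution import MODELS, center_star_msa, mean_region_distance, region_subalignment
from .records import read_fasta


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    # inputs (None disables whatever needs them)
    fasta: str | None = None
    reference_fasta: str | None = None
    tracks: str | None = None
    regions: str | None = None
    msa: str | None = None
    motifs: str | None = None
    scores: str | None = None
    edges: str | None = None
    annotation: str | None = None
    classes: str | None = None
    standards: str | None = None

    # stage toggles
    stages: list[str] = field(
        default_factory=lambda: ["disorder", "evolution", "phospho", "interactome", "hydro"]
    )

    # parameters
    reference_id: str | None = None
    focus: str | None = None
    threshold: float = 0.5
    min_len: int = 4
    boundary: str = "methods"
    model: str = "jtt"
    consensus: str = "minimal"
    fdr: float = 0.05
    n_boot: int = 10_000
    elution: float | None = None
    theoretical_mass: float | None = None
    seed: int = 0
    synthetic_demo: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(cfg: RunConfig, stage: str, attr: str) -> str:
    value = getattr(cfg, attr)
    if value is None:
        raise ValueError(f"stage {stage!r} requires the {attr!r} input")
    return value


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the enabled stages in dependency order and build the report."""
    report: dict[str, Any] = {
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "inputs": {},
        "stages": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    workdir = None
    if cfg.synthetic_demo:
        if outdir is None:
            raise ValueError("the synthetic demo needs an output directory")
        workdir = outdir / "synthetic_inputs"
        workdir.mkdir(exist_ok=True)
        cfg = _materialize_demo(cfg, workdir)

    for attr in ("fasta", "reference_fasta", "tracks", "regions", "msa", "motifs",
                 "scores", "edges", "annotation", "classes", "standards"):
        path = getattr(cfg, attr)
        if path is not None:
            report["inputs"][attr] = _sha256(path)

    records = read_fasta(cfg.fasta) if cfg.fasta else None
    region_set = None

    if "disorder" in cfg.stages:
        _require(cfg, "disorder", "fasta")
        stage: dict[str, Any] = {}
        focus_rec = records[0]
        point = disorder.ch_point(focus_rec, boundary=cfg.boundary)
        label, margin = disorder.ch_classify(point)
        stage["ch"] = {"h": point.h, "q": point.q, "label": label, "margin": margin}
        if cfg.reference_fasta:
            profile = disorder.fractional_difference_profile(
                records, read_fasta(cfg.reference_fasta),
                n_boot=cfg.n_boot, seed=cfg.seed,
            )
            enriched = profile.table.query("d > 0 and not undefined").index.tolist()
            depleted = profile.table.query("d < 0 and not undefined").index.tolist()
            stage["composition"] = {"enriched": enriched, "depleted": depleted}
            if outdir is not None:
                profile.table.to_csv(outdir / "composition_profile.tsv", sep="\t")
        if cfg.tracks:
            track = io.read_score_track(cfg.tracks, focus_rec.id)
        else:
            track = disorder.disorder_track_standin(focus_rec)
            stage["track"] = "flexibility stand-in (no external track supplied)"
        region_set = disorder.segment_regions(track, cfg.threshold, cfg.min_len,
                                              sequence_length=len(focus_rec))
        stage["regions"] = [
            {"start": s, "end": e, "label": lab} for s, e, lab in region_set.regions
        ]
        if outdir is not None:
            io.write_regions(region_set, outdir / "regions.tsv")
        report["stages"]["disorder"] = stage

    if "hydro" in cfg.stages:
        _require(cfg, "hydro", "standards")
        if cfg.elution is None or cfg.theoretical_mass is None:
            raise ValueError("stage 'hydro' requires the 'elution' and 'theoretical_mass' parameters")
        cal = hydro.fit_gf_calibration(io.read_standards(cfg.standards))
        est = hydro.apparent_mass(cal, cfg.elution)
        r_app = hydro.hydrodynamic_radius(est.mass_da, "native")
        r_nat = hydro.hydrodynamic_radius(cfg.theoretical_mass, "native")
        call = hydro.classify_conformation(r_nat, r_app)
        report["stages"]["hydro"] = {
            "calibration": {"slope": cal.slope, "intercept": cal.intercept, "r2": cal.r2},
            "apparent_mass_da": est.mass_da,
            "extrapolated": est.extrapolated,
            "r_apparent_A": r_app,
            "r_native_A": r_nat,
            "increase_pct": call.increase_pct,
            "call": call.call,
        }

    if "evolution" in cfg.stages:
        if cfg.msa:
            aln = _read_aligned_fasta(cfg.msa)
        else:
            _require(cfg, "evolution", "fasta")
            aln = center_star_msa(records)
        if cfg.regions:
            region_set = io.read_regions(cfg.regions)
        if region_set is None:
            raise ValueError(
                "stage 'evolution' requires a 'regions' input when the "
                "'disorder' segmentation stage is disabled"
            )
        reference_id = cfg.reference_id or region_set.protein_id
        stage = {"reference": reference_id, "regions": {}}
        by_label: dict[str, list[float]] = {}
        for start, end, lab in region_set.regions:
            sub = region_subalignment(aln, reference_id, start, end)
            means = {}
            for model in MODELS:
                est = mean_region_distance(sub, model)
                means[model] = est.mean
            stage["regions"][f"{lab}_{start}_{end}"] = means
            by_label.setdefault(lab, []).append(means[cfg.model])
        if {"ordered", "disordered"} <= set(by_label):
            import numpy as _np

            stage["disordered_over_ordered_ratio"] = float(
                _np.mean(by_label["disordered"]) / _np.mean(by_label["ordered"])
            )
        report["stages"]["evolution"] = stage

    if "phospho" in cfg.stages:
        _require(cfg, "phospho", "fasta")
        focus_rec = records[0]
        found = motifs.scan_cdk_sites(focus_rec, cfg.consensus)
        stage = {"n_sites": len(found), "positions": [s.position for s in found]}
        if cfg.motifs:
            motif_list = [m for m in io.read_motifs(cfg.motifs) if m.protein_id == focus_rec.id]
            buckets = motifs.assign_sites_to_motifs(found, motif_list)
            stage["per_motif"] = {name: len(ss) for name, ss in buckets.items()}
        if cfg.scores:
            scored = io.read_phosphosites(cfg.scores)
            ranking = motifs.rank_phospho_rhythm(scored)
            stage["rhythm"] = [s.position for s in ranking.sites]
        report["stages"]["phospho"] = stage

    if "interactome" in cfg.stages:
        _require(cfg, "interactome", "edges")
        if cfg.focus is None:
            raise ValueError("stage 'interactome' requires the 'focus' parameter")
        edges = io.read_edges(cfg.edges)
        assignment = network.assign_shells(edges, cfg.focus)
        stage = {"shell_sizes": assignment.counts}
        if cfg.annotation:
            annotation = io.read_annotation(cfg.annotation)
            background = {assignment.focus} | set(assignment.levels)
            enr = network.enrich_terms(
                set(assignment.levels), annotation, background, fdr=cfg.fdr
            )
            stage["significant_terms"] = enr.loc[enr["significant"], "term"].tolist()
            if outdir is not None:
                enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        if outdir is not None:
            classes = io.read_classes(cfg.classes) if cfg.classes else {}
            network.export_graph(
                assignment, edges, classes,
                sif_path=outdir / "interactome.sif",
                graphml_path=outdir / "interactome.graphml",
            )
        report["stages"]["interactome"] = stage

    validate_report(report)
    if outdir is not None:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _materialize_demo(cfg: RunConfig, workdir: Path) -> RunConfig:
    """Generate a full set of synthetic inputs and point the config at them."""
    from dataclasses import replace

    from .records import write_fasta

    seed = cfg.seed
    rec = synthetic.whi5_like_sequence()
    fasta = workdir / "query.fasta"
    write_fasta([rec], fasta)
    ref = synthetic.sample_sequence(
        synthetic.composition_preset("globular"), 5000, seed, record_id="globular_ref"
    )
    ref_fasta = workdir / "reference.fasta"
    write_fasta([ref], ref_fasta)

    fam = synthetic.simulate_family(synthetic.FamilyConfig(seed=seed))
    msa = workdir / "family_msa.fasta"
    from .records import ProteinRecord

    write_fasta([ProteinRecord(i, s) for i, s in fam.alignment.records], msa)
    regions = workdir / "family_regions.tsv"
    io.write_regions(fam.regions, regions)

    mot = workdir / "motifs.tsv"
    import pandas as pd

    pd.DataFrame(
        [
            {"protein_id": m.protein_id, "name": m.name, "start": m.start, "end": m.end}
            for m in synthetic.whi5_like_motifs()
        ]
    ).to_csv(mot, sep="\t", index=False)
    sites = [s.position for s in motifs.scan_cdk_sites(rec)]
    scores = workdir / "scores.tsv"
    synthetic.synth_phospho_table(sites, sites[::-1], noise_sd=0.0, seed=seed).to_csv(
        scores, sep="\t", index=False
    )

    net_edges, _ = synthetic.synth_interactome(synthetic.NetConfig(seed=seed))
    edges = workdir / "edges.tsv"
    io.write_edges(net_edges, edges)
    annotation = workdir / "annotation.tsv"
    pd.DataFrame(
        [{"term": "planted:firstshell", "protein_id": f"P1_{i}"} for i in range(5)]
        + [{"term": "planted:outer", "protein_id": f"OUT_{i}"} for i in range(10)]
    ).to_csv(annotation, sep="\t", index=False)

    standards = workdir / "standards.tsv"
    synthetic.synth_gf_standards(seed=seed).to_csv(standards, sep="\t", index=False)

    return replace(
        cfg,
        fasta=str(fasta),
        reference_fasta=str(ref_fasta),
        msa=str(msa),
        regions=str(regions),
        motifs=str(mot),
        scores=str(scores),
        edges=str(edges),
        annotation=str(annotation),
        standards=str(standards),
        focus=cfg.focus or "FOCUS",
        reference_id="leaf1",
        elution=cfg.elution if cfg.elution is not None else 11.3,
        theoretical_mass=cfg.theoretical_mass if cfg.theoretical_mass is not None else 34_020.0,
        n_boot=min(cfg.n_boot, 2000),
        synthetic_demo=False,
    )


def _read_aligned_fasta(path: str | Path):
    from Bio import SeqIO

    from .evolution import Alignment

    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    return Alignment(records=records)


def validate_report(report: dict[str, Any]) -> None:
    """Check a report against the bundled structural schema."""
    schema = json.loads(
        resources.files("idrscape.data").joinpath("report_schema.json").read_text()
    )
    _validate(report, schema, "report")


def _validate(obj: Any, schema: dict[str, Any], path: str) -> None:
    kind = schema.get("type")
    types = {"object": dict, "array": list, "string": str, "number": (int, float),
             "integer": int, "boolean": bool}
    if kind and not isinstance(obj, types[kind]):
        raise ValueError(f"{path}: expected {kind}, got {type(obj).__name__}")
    if kind == "object":
        for key in schema.get("required", []):
            if key not in obj:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _validate(obj[key], sub, f"{path}.{key}")
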