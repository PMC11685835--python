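"""Screening pipeline: mutate -> sample/ingest -> classify -> evaluate.

A run is declared in a YAML config: a NAC model, a variant source (an
explicit list/file or an enumeration rule) and a trajectory source
(external multi-model PDBs per variant, or the surrogate pocket sampler
with per-variant well perturbations).  Per-variant work is fail-soft:
a stage failure records a status and the run continues; every requested
variant ends in a terminal status (classified, unbuildable, no-NAC-pose
or failed).  Identical config + seed reproduces outputs byte-for-byte;
wall-times live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, NacscreenError
from .fixtures import make_pocket
from .model import NACModel, classify_trajectory, filter_poses, load_nac_model
from .mutation import (
    SideChainTemplateLibrary,
    Variant,
    apply_mutation,
    enumerate_single,
    parse_variant,
    positions_within_radius,
)
from .sampler import metropolis_sample, mutate_pocket
from .stats import (
    PopulationResult,
    PredictionRecord,
    VariantResult,
    aggregate_replicates,
    classify_vs_reference,
    confusion_table,
    population,
    prediction_accuracy,
    rank_variants,
    read_labels_tsv,
)
from .structure import AtomSelector, Structure, read_structure, read_trajectory, write_structure

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_run_config", "run_enumerate", "run_screen", "run_evaluate"]


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML schema in the docs)."""

    nac_model: str
    seed: int = 0
    replicates: int = 1
    output: str = "nacscreen-out"
    structure: str | None = None
    variant_list: list[str] | None = None
    variant_file: str | None = None
    enumerate_rule: dict | None = None
    sampler: dict | None = None
    trajectories: dict[str, list[str]] | None = None
    pose_filter: bool = False
    no_nac_pose_policy: str = "exclude"  # or "zero"
    build: bool = False
    clash_cap: int = 0
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.variant_list, self.variant_file, self.enumerate_rule)
            if s is not None
        ]
        if len(sources) != 1:
            raise ConfigError(
                "variants: exactly one of 'list', 'file' or 'enumerate' required"
            )
        if (self.sampler is None) == (self.trajectories is None):
            raise ConfigError(
                "exactly one trajectory source required: 'sampler' or 'trajectories'"
            )
        if self.replicates < 1:
            raise ConfigError(f"replicates must be >= 1, got {self.replicates}")
        if self.no_nac_pose_policy not in ("exclude", "zero"):
            raise ConfigError(
                f"no_nac_pose_policy must be 'exclude' or 'zero', "
                f"got {self.no_nac_pose_policy!r}"
            )


def load_run_config(path) -> RunConfig:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    allowed = {
        "nac_model", "seed", "replicates", "output", "structure", "variants",
        "sampler", "trajectories", "pose_filter", "no_nac_pose_policy",
        "build", "clash_cap",
    }
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "nac_model" not in doc:
        raise ConfigError(f"{path}: 'nac_model' is required")
    variants = doc.get("variants") or {}
    if not isinstance(variants, dict):
        raise ConfigError(f"{path}: 'variants' must be a mapping")
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    trajectories = doc.get("trajectories")
    if trajectories is not None:
        trajectories = {
            vid: [_resolve(p) for p in paths] for vid, paths in trajectories.items()
        }
    return RunConfig(
        nac_model=_resolve(doc["nac_model"]),
        seed=int(doc.get("seed", 0)),
        replicates=int(doc.get("replicates", 1)),
        output=_resolve(doc.get("output", "nacscreen-out")),
        structure=_resolve(doc["structure"]) if doc.get("structure") else None,
        variant_list=variants.get("list"),
        variant_file=_resolve(variants["file"]) if variants.get("file") else None,
        enumerate_rule=variants.get("enumerate"),
        sampler=doc.get("sampler"),
        trajectories=trajectories,
        pose_filter=bool(doc.get("pose_filter", False)),
        no_nac_pose_policy=doc.get("no_nac_pose_policy", "exclude"),
        build=bool(doc.get("build", False)),
        clash_cap=int(doc.get("clash_cap", 0)),
        raw=doc,
    )


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.raw, sort_keys=True).encode()
    ).hexdigest()[:16]


def _resolve_variants(config: RunConfig, structure: Structure | None) -> list[Variant]:
    if config.variant_list is not None:
        if not config.variant_list:
            raise ConfigError("variants.list is empty")
        return [parse_variant(v) for v in config.variant_list]
    if config.variant_file is not None:
        lines = Path(config.variant_file).read_text().splitlines()
        ids = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
        if not ids:
            raise ConfigError(f"variant file {config.variant_file} is empty")
        return [parse_variant(v) for v in ids]
    rule = config.enumerate_rule
    if structure is None:
        raise ConfigError("variants.enumerate requires a 'structure'")
    allowed = {"positions", "shell", "exclusions"}
    unknown = set(rule) - allowed
    if unknown:
        raise ConfigError(f"variants.enumerate: unknown keys {sorted(unknown)}")
    if "positions" in rule:
        positions = [int(p) for p in rule["positions"]]
    elif "shell" in rule:
        shell = rule["shell"]
        ligand = [
            AtomSelector(
                resid=int(s["resid"]), atom_name=str(s["atom_name"]),
                chain=s.get("chain"), entity=s.get("entity"),
            )
            for s in shell.get("ligand", [])
        ]
        positions = positions_within_radius(
            structure, ligand, float(shell.get("radius", 12.0))
        )
    else:
        raise ConfigError("variants.enumerate needs 'positions' or 'shell'")
    if not positions:
        raise ConfigError("variants.enumerate: empty position list")
    exclusions = [int(p) for p in rule.get("exclusions", [])]
    return enumerate_single(positions, exclusions, structure)


def run_enumerate(config: RunConfig) -> pd.DataFrame:
    """Enumerate the variant space into a manifest table.

    With ``build: true`` each variant is also built (rotamer grafting) and
    flagged buildable when its residual clash count is within
    ``clash_cap``; with ``build: false`` the structural columns stay NA.
    """
    structure = (
        read_structure(Path(config.structure).read_text(), id=config.structure)
        if config.structure
        else None
    )
    variants = _resolve_variants(config, structure)
    lib = SideChainTemplateLibrary()
    rows = []
    for v in variants:
        muts = sorted(v.mutations)
        row = {
            "variant_id": v.id,
            "position": muts[0].position if muts else "",
            "wt": muts[0].wt if muts else "",
            "new": muts[0].new if muts else "",
            "buildable": "",
            "clash_count": "",
        }
        if config.build and structure is not None and not v.is_wildtype:
            try:
                built = apply_mutation(structure, v, lib)
                clashes = built.annotations["clash_count"]
                row["buildable"] = clashes <= config.clash_cap
                row["clash_count"] = clashes
            except NacscreenError as exc:
                row["buildable"] = False
                row["clash_count"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _replicate_seed(base_seed: int, variant_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence([base_seed, variant_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sampler_trajectories(config: RunConfig, variant: Variant, vi: int):
    spec = dict(config.sampler)
    pocket_params = dict(spec.get("pocket", {}))
    effects = spec.get("variant_effects", {}) or {}
    pocket = make_pocket(
        d0=float(pocket_params.get("d0", 3.5)),
        k=float(pocket_params.get("k", 4.0)),
        wall_radius=float(pocket_params.get("wall_radius", 2.0)),
        wall_k=float(pocket_params.get("wall_k", 10.0)),
        temperature=float(pocket_params.get("temperature", 1.0)),
    )
    eff = effects.get(variant.id, {})
    pocket = mutate_pocket(
        pocket,
        delta_d0=float(eff.get("delta_d0", 0.0)),
        delta_k=float(eff.get("delta_k", 0.0)),
    )
    for r in range(config.replicates):
        yield metropolis_sample(
            pocket,
            n_steps=int(spec.get("n_steps", 20000)),
            stride=int(spec.get("stride", 10)),
            seed=_replicate_seed(config.seed, vi, r),
            translation_width=float(spec.get("translation_width", 0.3)),
            rotation_width_deg=float(spec.get("rotation_width_deg", 5.0)),
        )


def _file_trajectories(config: RunConfig, variant: Variant):
    paths = config.trajectories.get(variant.id)
    if not paths:
        raise ConfigError(f"no trajectory files configured for variant {variant.id}")
    for p in paths:
        yield read_trajectory(Path(p).read_text(), id=p)


def run_screen(config: RunConfig) -> dict:
    """Execute the full screen and write ranking + traces + manifest.

    Returns the manifest dict.  Outputs under ``config.output``:
    ``ranking.tsv`` / ``ranking.json`` (rank, variant, mean population,
    WT-relative call), ``traces/<variant>.tsv`` (per-frame active flags
    per replicate), ``manifest.json`` (config hash, seeds, statuses,
    stage wall-times).
    """
    t0 = time.perf_counter()
    outdir = Path(config.output)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    model = load_nac_model(config.nac_model)
    structure = (
        read_structure(Path(config.structure).read_text(), id=config.structure)
        if config.structure
        else None
    )
    variants = _resolve_variants(config, structure)
    lib = SideChainTemplateLibrary()

    statuses: dict[str, str] = {}
    timings: dict[str, float] = {}
    results: list[VariantResult] = []
    zero_scored: list[str] = []

    for vi, variant in enumerate(variants):
        tv = time.perf_counter()
        vid = variant.id
        try:
            if config.build and structure is not None and not variant.is_wildtype:
                built = apply_mutation(structure, variant, lib)
                if built.annotations["clash_count"] > config.clash_cap:
                    statuses[vid] = "unbuildable"
                    logger.info(
                        "%s: unbuildable (%d residual clashes)",
                        vid, built.annotations["clash_count"],
                    )
                    continue
                (outdir / "traces" / f"{vid}.pdb").write_text(write_structure(built))

            trajs = (
                _sampler_trajectories(config, variant, vi)
                if config.sampler is not None
                else _file_trajectories(config, variant)
            )
            pops = []
            trace_rows = []
            no_pose_total = None
            for r, traj in enumerate(trajs):
                if config.pose_filter:
                    n_in = len(traj)
                    traj = filter_poses(model, traj)
                    if len(traj) == 0:
                        no_pose_total = n_in
                        break
                mask = classify_trajectory(model, traj)
                pops.append(population(mask, source=f"{vid}/rep{r}"))
                for f, flag in enumerate(mask.flags):
                    trace_rows.append((r, f, int(flag)))
            if no_pose_total is not None:
                if config.no_nac_pose_policy == "zero":
                    zero_scored.append(vid)
                    results.append(
                        VariantResult(
                            variant_id=vid,
                            replicates=(
                                PopulationResult(
                                    P=0.0, n_active=0, n_total=no_pose_total,
                                    source=f"{vid}/no-NAC-pose",
                                ),
                            ),
                        )
                    )
                statuses[vid] = "no-NAC-pose"
                continue
            trace = pd.DataFrame(trace_rows, columns=["replicate", "frame", "active"])
            trace.to_csv(outdir / "traces" / f"{vid}.tsv", sep="\t", index=False)
            results.append(aggregate_replicates(pops, variant_id=vid))
            statuses[vid] = "classified"
        except ConfigError:
            raise
        except NacscreenError as exc:
            statuses[vid] = "failed"
            logger.error("%s: stage failure: %s", vid, exc)
        finally:
            timings[vid] = round(time.perf_counter() - tv, 6)

    reference = "WT" if any(r.variant_id == "WT" for r in results) else None
    if results:
        table = rank_variants(results, reference_id=reference)
        (outdir / "ranking.tsv").write_text(table.to_tsv())
        (outdir / "ranking.json").write_text(
            json.dumps(table.to_records(), indent=2, sort_keys=True, default=_json_default)
            + "\n"
        )

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "replicates": config.replicates,
        "statuses": statuses,
        "n_requested": len(variants),
        "n_classified": sum(1 for s in statuses.values() if s == "classified"),
        "n_unbuildable": sum(1 for s in statuses.values() if s == "unbuildable"),
        "n_no_nac_pose": sum(1 for s in statuses.values() if s == "no-NAC-pose"),
        "n_failed": sum(1 for s in statuses.values() if s == "failed"),
        "zero_scored": zero_scored,
        "wall_time_s": {"total": round(time.perf_counter() - t0, 6), **timings},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_evaluate(
    predictions_path, labels_path, reference_id: str = "WT"
) -> dict:
    """Join predicted populations with experimental labels and score accuracy.

    ``predictions_path`` is a 2-column TSV (variant id, population) that
    must include the reference row; every other variant is classified
    strictly against the reference and matched to its experimental
    higher/lower label.  Unmatched ids on either side are an error.
    """
    pred_text = Path(predictions_path).read_text()
    pops: dict[str, float] = {}
    for lineno, line in enumerate(pred_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ConfigError(
                f"predictions line {lineno}: expected 2 tab-separated columns"
            )
        try:
            pops[parts[0].strip()] = float(parts[1])
        except ValueError:
            if lineno == 1:
                continue  # header row
            raise ConfigError(
                f"predictions line {lineno}: population {parts[1]!r} is not a number"
            ) from None
    if reference_id not in pops:
        raise ConfigError(f"predictions must include the reference {reference_id!r}")
    labels = read_labels_tsv(Path(labels_path).read_text())
    ref_p = pops.pop(reference_id)
    labels.pop(reference_id, None)
    missing_labels = sorted(set(pops) - set(labels))
    missing_preds = sorted(set(labels) - set(pops))
    if missing_labels or missing_preds:
        raise ConfigError(
            f"id mismatch between predictions and labels; "
            f"without labels: {missing_labels}; without predictions: {missing_preds}"
        )
    if not pops:
        raise ConfigError("no variants shared between predictions and labels")
    records = [
        PredictionRecord(
            variant_id=vid,
            predicted=classify_vs_reference(p, ref_p),
            experimental=labels[vid],
        )
        for vid, p in sorted(pops.items())
    ]
    table = confusion_table(records)
    return {
        "n_records": len(records),
        "n_correct": sum(r.correct for r in records),
        "accuracy": prediction_accuracy(records),
        "reference": reference_id,
        "reference_population": ref_p,
        "confusion": {
            exp: {pred: int(table.loc[exp, pred]) for pred in table.columns}
            for exp in table.index
        },
    }
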