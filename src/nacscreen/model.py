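"""Near-attack-conformation (NAC) models and frame classification.

A NAC model names the geometry a Michaelis complex must adopt for the
chemistry to be poised to happen: the bond-forming atom pair in van der
Waals contact (or inside an explicit cutoff such as 4 Angstrom for an
epoxide-hydrolase nucleophilic attack) and, optionally, the attack angle
near its transition-state value.  A frame is *active* iff every criterion
holds — criteria combine by conjunction only.  Trajectory frames and
docked poses are classified identically.

Comparison conventions (documented, strict): distances pass on strict
``<`` of the effective threshold; angles pass on ``|measured - target| <=
tolerance``.  Equality at a float boundary is astronomically unlikely
either way; the convention only fixes the semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError, EmptyInputError, SelectorError
from .structure import (
    AtomSelector,
    Structure,
    Trajectory,
    resolve_selector,
    vdw_radius,
)

__all__ = [
    "DistanceCriterion",
    "AngleCriterion",
    "NACModel",
    "CriterionResult",
    "FrameEvaluation",
    "ActiveMask",
    "load_nac_model",
    "loads_nac_model",
    "dump_nac_model",
    "effective_threshold",
    "evaluate_frame",
    "classify_trajectory",
    "filter_poses",
    "DEFAULT_ANGLE_TOLERANCE",
]

logger = logging.getLogger(__name__)

#: Default half-width around the transition-state angle when a model omits
#: one.  Our default; "similar to the transition state" is not quantified
#: in the NAC literature we follow.
DEFAULT_ANGLE_TOLERANCE = 20.0

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DistanceCriterion:
    """Bond-forming pair distance must be < threshold (strict).

    ``threshold_mode`` is ``"explicit"`` (a stated cutoff in Angstrom, e.g.
    4.0 for nucleophile-to-epoxide-carbon) or ``"vdw_sum"`` (sum of the two
    atoms' Bondi radii, resolved lazily against a structure).
    """

    a: AtomSelector
    b: AtomSelector
    threshold_mode: str = "vdw_sum"
    threshold: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("explicit", "vdw_sum"):
            raise ConfigError(
                f"criterion {self.label!r}: threshold_mode must be "
                f"'explicit' or 'vdw_sum', got {self.threshold_mode!r}"
            )
        if self.threshold_mode == "explicit":
            if self.threshold is None:
                raise ConfigError(
                    f"criterion {self.label!r}: explicit mode requires a threshold"
                )
            if self.threshold <= 0:
                raise ConfigError(
                    f"criterion {self.label!r}: threshold must be > 0, "
                    f"got {self.threshold}"
                )


@dataclass(frozen=True)
class AngleCriterion:
    """Attack angle at ``vertex`` must lie within target +/- tolerance degrees."""

    a: AtomSelector
    vertex: AtomSelector
    c: AtomSelector
    target_deg: float
    tolerance_deg: float = DEFAULT_ANGLE_TOLERANCE
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.target_deg <= 180.0):
            raise ConfigError(
                f"criterion {self.label!r}: target angle must be in (0, 180], "
                f"got {self.target_deg}"
            )
        if self.tolerance_deg <= 0:
            raise ConfigError(
                f"criterion {self.label!r}: tolerance must be > 0, "
                f"got {self.tolerance_deg}"
            )


@dataclass(frozen=True)
class NACModel:
    """A named conjunction of distance and angle criteria."""

    name: str
    distance_criteria: tuple[DistanceCriterion, ...] = ()
    angle_criteria: tuple[AngleCriterion, ...] = ()

    def __post_init__(self) -> None:
        if not self.distance_criteria and not self.angle_criteria:
            raise ConfigError(f"model {self.name!r}: at least one criterion required")
        object.__setattr__(self, "distance_criteria", tuple(self.distance_criteria))
        object.__setattr__(self, "angle_criteria", tuple(self.angle_criteria))

    @property
    def criteria(self):
        return self.distance_criteria + self.angle_criteria


@dataclass(frozen=True)
class CriterionResult:
    label: str
    measured: float
    threshold: float
    passed: bool


@dataclass(frozen=True)
class FrameEvaluation:
    """Per-criterion measurements and the conjunctive active flag."""

    results: tuple[CriterionResult, ...]
    active: bool


@dataclass
class ActiveMask:
    """Ordered per-frame active flags for one trajectory or pose set."""

    flags: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("ActiveMask flags must be one-dimensional")

    def __len__(self) -> int:
        return int(self.flags.shape[0])


# ---------------------------------------------------------------------------
# YAML schema


def _selector_from_dict(d: dict, path: str) -> AtomSelector:
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: selector must be a mapping, got {type(d).__name__}")
    allowed = {"resid", "atom_name", "chain", "resname", "entity", "icode"}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown selector keys {sorted(unknown)}")
    for key in ("resid", "atom_name"):
        if key not in d:
            raise ConfigError(f"{path}: selector missing required key {key!r}")
    try:
        return AtomSelector(
            resid=int(d["resid"]),
            atom_name=str(d["atom_name"]),
            chain=d.get("chain"),
            resname=d.get("resname"),
            entity=d.get("entity"),
            icode=d.get("icode", ""),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _selector_to_dict(sel: AtomSelector) -> dict:
    d: dict = {"resid": sel.resid, "atom_name": sel.atom_name}
    if sel.chain is not None:
        d["chain"] = sel.chain
    if sel.resname is not None:
        d["resname"] = sel.resname
    if sel.entity is not None:
        d["entity"] = sel.entity
    if sel.icode:
        d["icode"] = sel.icode
    return d


def loads_nac_model(text: str) -> NACModel:
    """Parse a NAC model from YAML text (see docs for the schema)."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    return _model_from_dict(doc)


def load_nac_model(path) -> NACModel:
    """Load a NAC model from a YAML file path."""
    with open(path) as fh:
        return loads_nac_model(fh.read())


def _model_from_dict(doc) -> NACModel:
    if not isinstance(doc, dict):
        raise ConfigError("model document must be a mapping")
    allowed = {"name", "criteria", "schema_version"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"model: unknown keys {sorted(unknown)}")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"model: unsupported schema_version {version}")
    name = doc.get("name")
    if not name:
        raise ConfigError("model: 'name' is required")
    raw = doc.get("criteria")
    if not raw:
        raise ConfigError("model.criteria: at least one criterion required")
    if not isinstance(raw, list):
        raise ConfigError("model.criteria: must be a list")
    dists: list[DistanceCriterion] = []
    angles: list[AngleCriterion] = []
    for idx, c in enumerate(raw):
        path = f"model.criteria[{idx}]"
        if not isinstance(c, dict):
            raise ConfigError(f"{path}: must be a mapping")
        kind = c.get("kind")
        if kind == "distance":
            allowed_keys = {"kind", "label", "a", "b", "mode", "threshold"}
            unknown = set(c) - allowed_keys
            if unknown:
                raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
            mode = c.get("mode", "vdw_sum")
            if mode == "explicit" and "threshold" not in c:
                raise ConfigError(f"{path}: explicit mode requires 'threshold'")
            try:
                dists.append(
                    DistanceCriterion(
                        a=_selector_from_dict(c.get("a"), f"{path}.a"),
                        b=_selector_from_dict(c.get("b"), f"{path}.b"),
                        threshold_mode=mode,
                        threshold=c.get("threshold"),
                        label=c.get("label", f"D{idx}"),
                    )
                )
            except ConfigError as exc:
                raise ConfigError(f"{path}: {exc}") from None
        elif kind == "angle":
            allowed_keys = {"kind", "label", "a", "vertex", "c", "target", "tolerance"}
            unknown = set(c) - allowed_keys
            if unknown:
                raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
            if "target" not in c:
                raise ConfigError(f"{path}: angle criterion requires 'target'")
            try:
                angles.append(
                    AngleCriterion(
                        a=_selector_from_dict(c.get("a"), f"{path}.a"),
                        vertex=_selector_from_dict(c.get("vertex"), f"{path}.vertex"),
                        c=_selector_from_dict(c.get("c"), f"{path}.c"),
                        target_deg=float(c["target"]),
                        tolerance_deg=float(c.get("tolerance", DEFAULT_ANGLE_TOLERANCE)),
                        label=c.get("label", f"A{idx}"),
                    )
                )
            except ConfigError as exc:
                raise ConfigError(f"{path}: {exc}") from None
        else:
            raise ConfigError(f"{path}: kind must be 'distance' or 'angle', got {kind!r}")
    return NACModel(name=str(name), distance_criteria=tuple(dists), angle_criteria=tuple(angles))


def dump_nac_model(model: NACModel) -> str:
    """Serialize a NAC model back to YAML (round-trips with ``loads_nac_model``)."""
    criteria: list[dict] = []
    for d in model.distance_criteria:
        entry: dict = {
            "kind": "distance",
            "label": d.label,
            "a": _selector_to_dict(d.a),
            "b": _selector_to_dict(d.b),
            "mode": d.threshold_mode,
        }
        if d.threshold is not None:
            entry["threshold"] = float(d.threshold)
        criteria.append(entry)
    for a in model.angle_criteria:
        criteria.append(
            {
                "kind": "angle",
                "label": a.label,
                "a": _selector_to_dict(a.a),
                "vertex": _selector_to_dict(a.vertex),
                "c": _selector_to_dict(a.c),
                "target": float(a.target_deg),
                "tolerance": float(a.tolerance_deg),
            }
        )
    return yaml.safe_dump(
        {"schema_version": SCHEMA_VERSION, "name": model.name, "criteria": criteria},
        sort_keys=False,
    )


# ---------------------------------------------------------------------------
# Evaluation


def effective_threshold(criterion: DistanceCriterion, structure: Structure) -> float:
    """Distance cutoff in Angstrom: explicit value, or the Bondi vdW sum."""
    if criterion.threshold_mode == "explicit":
        return float(criterion.threshold)
    ia = resolve_selector(structure, criterion.a)
    ib = resolve_selector(structure, criterion.b)
    return vdw_radius(structure.atoms[ia].element) + vdw_radius(
        structure.atoms[ib].element
    )


def _resolve_or_label(structure: Structure, sel: AtomSelector, label: str) -> int:
    try:
        return resolve_selector(structure, sel)
    except SelectorError as exc:
        raise SelectorError(f"criterion {label!r}: {exc}") from exc


def _resolved_indices(model: NACModel, topology: Structure):
    d_idx = [
        (_resolve_or_label(topology, c.a, c.label), _resolve_or_label(topology, c.b, c.label))
        for c in model.distance_criteria
    ]
    a_idx = [
        (
            _resolve_or_label(topology, c.a, c.label),
            _resolve_or_label(topology, c.vertex, c.label),
            _resolve_or_label(topology, c.c, c.label),
        )
        for c in model.angle_criteria
    ]
    thresholds = [effective_threshold(c, topology) for c in model.distance_criteria]
    return d_idx, a_idx, thresholds


def evaluate_frame(model: NACModel, topology: Structure, frame: np.ndarray) -> FrameEvaluation:
    """Evaluate every criterion on a single frame; active = conjunction."""
    frame = np.asarray(frame, dtype=float)
    d_idx, a_idx, thresholds = _resolved_indices(model, topology)
    results: list[CriterionResult] = []
    for crit, (i, j), thr in zip(model.distance_criteria, d_idx, thresholds):
        measured = float(np.linalg.norm(frame[i] - frame[j]))
        results.append(CriterionResult(crit.label, measured, thr, measured < thr))
    for crit, (i, j, k) in zip(model.angle_criteria, a_idx):
        u = frame[i] - frame[j]
        v = frame[k] - frame[j]
        cosine = np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0
        )
        measured = float(np.degrees(np.arccos(cosine)))
        results.append(
            CriterionResult(
                crit.label,
                measured,
                crit.tolerance_deg,
                abs(measured - crit.target_deg) <= crit.tolerance_deg,
            )
        )
    return FrameEvaluation(tuple(results), all(r.passed for r in results))


def classify_trajectory(model: NACModel, trajectory: Trajectory) -> ActiveMask:
    """Per-frame active/inactive flags for a whole trajectory (vectorized).

    Deterministic and order-preserving: ``flags[i]`` equals
    ``evaluate_frame(model, topology, frames[i]).active``.
    """
    if len(trajectory) == 0:
        raise EmptyInputError("cannot classify an empty trajectory")
    top = trajectory.topology
    d_idx, a_idx, thresholds = _resolved_indices(model, top)
    frames = trajectory.frames
    active = np.ones(len(trajectory), dtype=bool)
    for (i, j), thr in zip(d_idx, thresholds):
        dist = np.linalg.norm(frames[:, i, :] - frames[:, j, :], axis=1)
        active &= dist < thr
    for crit, (i, j, k) in zip(model.angle_criteria, a_idx):
        u = frames[:, i, :] - frames[:, j, :]
        v = frames[:, k, :] - frames[:, j, :]
        cosine = np.einsum("fi,fi->f", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
        active &= np.abs(ang - crit.target_deg) <= crit.tolerance_deg
    return ActiveMask(active, source=trajectory.topology.id)


def filter_poses(model: NACModel, poses: Trajectory) -> Trajectory:
    """Keep exactly the docked poses whose geometry satisfies the NAC model.

    Pose order is preserved.  An empty result is legal (a variant may
    produce no catalytically consistent pose) and is flagged in the run
    log so pipelines can apply their no-NAC-pose policy.
    """
    mask = classify_trajectory(model, poses)
    kept = np.flatnonzero(mask.flags)
    if kept.size == 0:
        logger.warning(
            "no pose of %d satisfies NAC model %r", len(poses), model.name
        )
        return _empty_like(poses)
    return poses.subset(kept.tolist())


def _empty_like(poses: Trajectory) -> Trajectory:
    # Trajectory requires >= 1 frame; an empty pose set is represented by
    # a zero-frame container constructed without re-validation.
    empty = Trajectory.__new__(Trajectory)
    empty.topology = poses.topology
    empty.frames = np.empty((0, len(poses.topology.atoms), 3))
    empty.frame_labels = [] if poses.frame_labels is not None else None
    return empty
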