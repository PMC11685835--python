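"""Surrogate conformational samplers.

Real NAC screening sits downstream of docking and MD engines.  This
module provides two desk-scale stand-ins:

* :func:`synth_trajectory` — constructs an ensemble with an *exact*
  number of active frames by placing the criterion atoms just inside or
  outside their thresholds, with jitter bounded so it provably cannot
  flip a frame's class.  Used to test the classifier and population
  statistics against known ground truth.

* :func:`metropolis_sample` — a rigid-body Metropolis Monte Carlo sampler
  of a ligand in a model pocket (harmonic well on the attack-pair
  distance plus soft repulsive walls).  Its equilibrium ensemble has a
  closed-form active population (:func:`nac_probability`), giving an
  end-to-end pipeline with an analytic oracle.  It emulates the *shape*
  of an MD ensemble (correlated frames, tunable well), not its physics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from .errors import ConfigError
from .model import NACModel, effective_threshold, evaluate_frame
from .structure import Structure, Trajectory, resolve_selector

__all__ = [
    "SyntheticSpec",
    "PocketModel",
    "synth_trajectory",
    "metropolis_sample",
    "mutate_pocket",
    "nac_probability",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for an exact-fraction synthetic ensemble."""

    topology: Structure
    model: NACModel
    n_frames: int
    active_fraction: float
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ConfigError(
                f"active_fraction must be in [0, 1], got {self.active_fraction}"
            )
        if self.n_frames < 1:
            raise ConfigError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.jitter < 0:
            raise ConfigError(f"jitter must be >= 0, got {self.jitter}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _place_distance(coords, ia, ib, target_d):
    """Move atom b along the a->b direction to the target distance."""
    direction = _unit(coords[ib] - coords[ia])
    coords[ib] = coords[ia] + direction * target_d


def _place_angle(coords, ia, iv, ic, target_deg):
    """Move atom a so the angle at the vertex equals the target."""
    v = coords[iv]
    arm_c = coords[ic] - v
    la = np.linalg.norm(coords[ia] - v) or 1.5
    e1 = _unit(arm_c)
    # perpendicular component of the current a-arm, or any perpendicular
    perp = coords[ia] - v - np.dot(coords[ia] - v, e1) * e1
    if np.linalg.norm(perp) < 1e-9:
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, e1)) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        perp = trial - np.dot(trial, e1) * e1
    e2 = _unit(perp)
    theta = math.radians(target_deg)
    coords[ia] = v + la * (math.cos(theta) * e1 + math.sin(theta) * e2)


def _angle_jitter_bound_deg(coords, ia, iv, ic, jitter) -> float:
    """Worst-case angle change (degrees) when every atom moves <= jitter."""
    la = np.linalg.norm(coords[ia] - coords[iv])
    lc = np.linalg.norm(coords[ic] - coords[iv])
    bound = 0.0
    for arm in (la, lc):
        x = min(1.0, 2.0 * jitter / arm) if arm > 0 else 1.0
        bound += math.degrees(math.asin(x))
    return bound


def synth_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Build an ensemble with exactly ``round(f * n)`` active frames.

    Active frames place each distance pair at threshold * (1 - margin)
    and each angle at its target; inactive frames violate the first
    criterion by the same margin on the other side.  The margin exceeds
    the worst-case jitter displacement, so the constructed class is
    guaranteed; this is re-verified on the jitter-free base frames and a
    :class:`ConfigError` is raised if criteria could not be satisfied
    jointly (e.g. criteria sharing atoms that fight each other).
    """
    top = spec.topology
    model = spec.model
    j = spec.jitter
    base = top.coords

    d_idx = [
        (resolve_selector(top, c.a), resolve_selector(top, c.b))
        for c in model.distance_criteria
    ]
    a_idx = [
        (resolve_selector(top, c.a), resolve_selector(top, c.vertex), resolve_selector(top, c.c))
        for c in model.angle_criteria
    ]
    thresholds = [effective_threshold(c, top) for c in model.distance_criteria]

    # --- active base frame
    active = base.copy()
    for (ia, ib), thr in zip(d_idx, thresholds):
        delta = 2.0 * j + 0.05 * thr
        target = thr - delta
        if target <= 0:
            raise ConfigError(
                f"jitter {j} too large: active distance {target:.3f} <= 0 "
                f"for threshold {thr:.3f}"
            )
        _place_distance(active, ia, ib, target)
    for crit, (ia, iv, ic) in zip(model.angle_criteria, a_idx):
        _place_angle(active, ia, iv, ic, crit.target_deg)
        if _angle_jitter_bound_deg(active, ia, iv, ic, j) >= crit.tolerance_deg:
            raise ConfigError(
                f"jitter {j} too large for angle criterion {crit.label!r}: "
                f"cannot guarantee the class boundary"
            )

    # --- inactive base frame: violate the first criterion decisively
    inactive = active.copy()
    if d_idx:
        (ia, ib), thr = d_idx[0], thresholds[0]
        _place_distance(inactive, ia, ib, thr + 2.0 * j + 0.05 * thr)
    else:
        crit, (ia, iv, ic) = model.angle_criteria[0], a_idx[0]
        bound = _angle_jitter_bound_deg(active, ia, iv, ic, j)
        up = crit.target_deg + crit.tolerance_deg + bound + 1.0
        down = crit.target_deg - crit.tolerance_deg - bound - 1.0
        if up <= 180.0:
            _place_angle(inactive, ia, iv, ic, up)
        elif down > 0.0:
            _place_angle(inactive, ia, iv, ic, down)
        else:
            raise ConfigError(
                f"angle criterion {crit.label!r}: no violating angle exists in (0, 180]"
            )

    # re-verify the jitter-free base frames (criteria may share atoms)
    if not evaluate_frame(model, top, active).active:
        raise ConfigError(
            "could not construct a frame satisfying all criteria jointly; "
            "criteria likely share atoms with conflicting placements"
        )
    if evaluate_frame(model, top, inactive).active:
        raise ConfigError("could not construct a decisively inactive frame")

    n_active = round(spec.active_fraction * spec.n_frames)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(spec.n_frames)
    labels = np.zeros(spec.n_frames, dtype=bool)
    labels[order[:n_active]] = True

    frames = np.empty((spec.n_frames, base.shape[0], 3))
    for f in range(spec.n_frames):
        frames[f] = active if labels[f] else inactive
        if j > 0:
            direction = rng.normal(size=(base.shape[0], 3))
            direction /= np.maximum(np.linalg.norm(direction, axis=1)[:, None], 1e-12)
            frames[f] = frames[f] + direction * rng.uniform(0, j, size=(base.shape[0], 1))
    return Trajectory(
        top, frames, frame_labels=["active" if x else "inactive" for x in labels]
    )


# ---------------------------------------------------------------------------
# Metropolis pocket sampler


@dataclass(frozen=True)
class PocketModel:
    """A rigid ligand in a model pocket.

    The energy (kT units) is a harmonic well on the attack-pair distance,
    ``0.5 * k * (d - d0)**2``, plus a soft repulsive wall
    ``wall_k * (wall_radius - r)**2`` for every anchor-ligand pair closer
    than ``wall_radius``.  ``d0`` is the well centre (Angstrom) and plays
    the role of a variant's preferred attack distance.
    """

    topology: Structure
    ligand_indices: tuple[int, ...]
    attack_anchor: int  # topology index of the enzyme attack atom
    attack_ligand: int  # topology index of the ligand attack atom
    d0: float
    k: float
    wall_radius: float = 2.0
    wall_k: float = 10.0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ConfigError(f"d0 must be > 0, got {self.d0}")
        if self.k <= 0:
            raise ConfigError(f"k must be > 0, got {self.k}")
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0, got {self.temperature}")
        if self.attack_ligand not in self.ligand_indices:
            raise ConfigError("attack_ligand must be one of the ligand atoms")
        if self.attack_anchor in self.ligand_indices:
            raise ConfigError("attack_anchor must be an enzyme (non-ligand) atom")

    def anchor_indices(self) -> list[int]:
        return [
            i for i in range(len(self.topology.atoms)) if i not in set(self.ligand_indices)
        ]

    def energy(self, ligand_coords: np.ndarray, anchor_coords: np.ndarray) -> float:
        rel = {g: n for n, g in enumerate(self.ligand_indices)}
        att = ligand_coords[rel[self.attack_ligand]]
        anchors = {g: n for n, g in enumerate(self.anchor_indices())}
        d = float(np.linalg.norm(att - anchor_coords[anchors[self.attack_anchor]]))
        e = 0.5 * self.k * (d - self.d0) ** 2
        diffs = ligand_coords[:, None, :] - anchor_coords[None, :, :]
        r = np.linalg.norm(diffs, axis=2)
        close = r < self.wall_radius
        if close.any():
            e += float(np.sum(self.wall_k * (self.wall_radius - r[close]) ** 2))
        return e


def mutate_pocket(pocket: PocketModel, delta_d0: float = 0.0, delta_k: float = 0.0) -> PocketModel:
    """A variant's pocket: the well centre and stiffness shifted by deltas."""
    new_d0 = pocket.d0 + delta_d0
    new_k = pocket.k + delta_k
    if new_d0 <= 0:
        raise ConfigError(f"mutated d0 must be > 0, got {new_d0}")
    if new_k <= 0:
        raise ConfigError(f"mutated k must be > 0, got {new_k}")
    return replace(pocket, d0=new_d0, k=new_k)


def metropolis_sample(
    pocket: PocketModel,
    n_steps: int,
    stride: int = 10,
    seed: int = 0,
    translation_width: float = 0.3,
    rotation_width_deg: float = 5.0,
    warn_window: int = 1000,
) -> Trajectory:
    """Rigid-body Metropolis sampling of the ligand in the pocket.

    Proposals translate the ligand by an isotropic Gaussian step (default
    0.3 Angstrom per axis) and, for multi-atom ligands, rotate it about
    its centroid (default 5 degrees).  Every ``stride``-th state is
    emitted.  Acceptance statistics land in ``annotations`` of the
    returned topology copy; zero acceptances over ``warn_window``
    consecutive steps triggers a non-ergodicity warning.
    """
    if stride < 1 or n_steps < stride:
        raise ConfigError(f"need n_steps >= stride >= 1, got {n_steps}, {stride}")
    rng = np.random.default_rng(seed)
    top = pocket.topology
    coords = top.coords
    anchor_idx = pocket.anchor_indices()
    anchor_coords = coords[anchor_idx]
    lig = coords[list(pocket.ligand_indices)].copy()
    multi = lig.shape[0] > 1

    energy = pocket.energy(lig, anchor_coords)
    beta = 1.0 / pocket.temperature
    n_frames = n_steps // stride
    frames = np.empty((n_frames, coords.shape[0], 3))
    accepted = 0
    since_accept = 0
    warned = False
    f = 0
    for step in range(n_steps):
        proposal = lig + rng.normal(0.0, translation_width, size=3)
        if multi:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.normal(0.0, math.radians(rotation_width_deg))
            rot = Rotation.from_rotvec(ang * axis)
            centroid = proposal.mean(axis=0)
            proposal = rot.apply(proposal - centroid) + centroid
        e_new = pocket.energy(proposal, anchor_coords)
        if e_new <= energy or rng.random() < math.exp(-beta * (e_new - energy)):
            lig, energy = proposal, e_new
            accepted += 1
            since_accept = 0
        else:
            since_accept += 1
            if since_accept >= warn_window and not warned:
                logger.warning(
                    "no accepted move in %d steps: sampler may be non-ergodic "
                    "for this pocket", warn_window,
                )
                warned = True
        if (step + 1) % stride == 0:
            frame = coords.copy()
            frame[list(pocket.ligand_indices)] = lig
            frames[f] = frame
            f += 1
    rate = accepted / n_steps
    logger.info("metropolis acceptance rate: %.3f over %d steps", rate, n_steps)
    out_top = Structure(list(top.atoms), id=top.id, annotations=dict(top.annotations))
    out_top.annotations["acceptance_rate"] = rate
    return Trajectory(out_top, frames[:f])


def nac_probability(pocket: PocketModel, threshold: float) -> float:
    """Closed-form equilibrium probability that the attack distance < threshold.

    For a freely translating ligand the radial marginal of the attack
    distance is ``p(d) ~ d**2 * exp(-E(d)/T)`` with
    ``E(d) = 0.5*k*(d-d0)**2 + wall(d)`` — the d**2 volume factor is the
    3-D translational Jacobian.  Exact for a single-atom ligand with one
    anchor; for larger pockets it is a reduced-coordinate approximation.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    T, k, d0 = pocket.temperature, pocket.k, pocket.d0

    def radial_energy(d: float) -> float:
        e = 0.5 * k * (d - d0) ** 2
        if d < pocket.wall_radius:
            e += pocket.wall_k * (pocket.wall_radius - d) ** 2
        return e

    def weight(d: float) -> float:
        return d * d * math.exp(-radial_energy(d) / T)

    sigma = math.sqrt(T / k)
    upper = d0 + 12.0 * sigma
    total, _ = quad(weight, 0.0, upper, limit=200)
    below, _ = quad(weight, 0.0, min(threshold, upper), limit=200)
    return below / total
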