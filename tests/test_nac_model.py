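import numpy as np
import pytest

from nacscreen import (
    ActiveMask,
    AtomSelector,
    ConfigError,
    DistanceCriterion,
    NACModel,
    SelectorError,
    Trajectory,
    classify_trajectory,
    dump_nac_model,
    effective_threshold,
    evaluate_frame,
    filter_poses,
    loads_nac_model,
)
from nacscreen.fixtures import random_geometry_case

from conftest import brute_force_active

ANEH_STYLE_YAML = """\
name: epoxide-attack
criteria:
  - kind: distance
    label: D_OD192-C2
    a: {resid: 192, atom_name: OD2, entity: enzyme}
    b: {resid: 900, atom_name: C2, entity: ligand}
    mode: explicit
    threshold: 4.0
  - kind: distance
    label: D_OH251-O1
    a: {resid: 251, atom_name: OH, entity: enzyme}
    b: {resid: 900, atom_name: O1, entity: ligand}
    mode: explicit
    threshold: 3.5
  - kind: distance
    label: D_OH314-O1
    a: {resid: 314, atom_name: OH, entity: enzyme}
    b: {resid: 900, atom_name: O1, entity: ligand}
    mode: explicit
    threshold: 3.5
"""


class TestSchema:
    def test_aneh_style_config(self):
        model = loads_nac_model(ANEH_STYLE_YAML)
        assert len(model.distance_criteria) == 3
        assert model.distance_criteria[0].threshold == 4.0
        assert model.distance_criteria[0].b.entity == "ligand"

    def test_zero_criteria_is_schema_error(self):
        with pytest.raises(ConfigError, match="criteri"):
            loads_nac_model("name: empty\ncriteria: []\n")

    def test_unknown_key_names_path(self):
        bad = ANEH_STYLE_YAML.replace("threshold: 4.0", "threshold: 4.0\n    bogus: 1")
        with pytest.raises(ConfigError, match=r"criteria\[0\]"):
            loads_nac_model(bad)

    def test_explicit_without_threshold_is_error(self):
        bad = ANEH_STYLE_YAML.replace("    threshold: 4.0\n", "")
        with pytest.raises(ConfigError, match="threshold"):
            loads_nac_model(bad)

    def test_nonpositive_tolerance_is_error(self):
        text = """\
name: m
criteria:
  - kind: angle
    a: {resid: 1, atom_name: X}
    vertex: {resid: 2, atom_name: Y}
    c: {resid: 3, atom_name: Z}
    target: 160
    tolerance: 0
"""
        with pytest.raises(ConfigError, match="tolerance"):
            loads_nac_model(text)

    def test_dump_load_roundtrip(self):
        model = loads_nac_model(ANEH_STYLE_YAML)
        assert loads_nac_model(dump_nac_model(model)) == model


class TestEffectiveThreshold:
    def test_explicit_verbatim(self, aneh_complex):
        structure, model = aneh_complex
        assert effective_threshold(model.distance_criteria[0], structure) == 4.0

    def test_vdw_sum_carbon_oxygen(self, aneh_complex):
        structure, _ = aneh_complex
        crit = DistanceCriterion(
            a=AtomSelector(resid=192, atom_name="OD2", entity="enzyme"),
            b=AtomSelector(resid=900, atom_name="C2", entity="ligand"),
            threshold_mode="vdw_sum",
        )
        assert effective_threshold(crit, structure) == pytest.approx(3.22)

    def test_missing_atom_propagates_selector_error(self, aneh_complex):
        structure, _ = aneh_complex
        crit = DistanceCriterion(
            a=AtomSelector(resid=999, atom_name="XX"),
            b=AtomSelector(resid=900, atom_name="C2", entity="ligand"),
            threshold_mode="vdw_sum",
        )
        with pytest.raises(SelectorError):
            effective_threshold(crit, structure)


def _place_pair_at(structure, model, d):
    """Frame with the first criterion pair moved to distance d, others kept active."""
    from nacscreen.sampler import SyntheticSpec, synth_trajectory

    spec = SyntheticSpec(
        topology=structure, model=model, n_frames=1, active_fraction=1.0,
        jitter=0.0, seed=0,
    )
    frame = synth_trajectory(spec).frames[0].copy()
    from nacscreen.structure import resolve_selector

    ia = resolve_selector(structure, model.distance_criteria[0].a)
    ib = resolve_selector(structure, model.distance_criteria[0].b)
    direction = frame[ib] - frame[ia]
    direction /= np.linalg.norm(direction)
    frame[ib] = frame[ia] + direction * d
    return frame


class TestEvaluateFrame:
    def test_inside_threshold_passes(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 3.9)
        ev = evaluate_frame(model, structure, frame)
        assert ev.results[0].measured == pytest.approx(3.9)
        assert ev.results[0].passed

    def test_exactly_at_threshold_fails_strict(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 4.0)
        ev = evaluate_frame(model, structure, frame)
        assert not ev.results[0].passed
        assert not ev.active

    def test_one_fail_means_inactive(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 5.0)
        ev = evaluate_frame(model, structure, frame)
        assert [r.passed for r in ev.results][0] is False
        assert any(r.passed for r in ev.results[1:])
        assert not ev.active

    def test_active_equals_conjunction(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 3.5)
        ev = evaluate_frame(model, structure, frame)
        assert ev.active == all(r.passed for r in ev.results)


class TestClassifyTrajectory:
    def test_matches_brute_force_oracle(self):
        top, model, frames = random_geometry_case(seed=1, n_frames=1000)
        mask = classify_trajectory(model, Trajectory(top, frames))
        expected = brute_force_active(model, top, frames)
        assert np.array_equal(mask.flags, expected)
        assert expected.any() and not expected.all()  # both classes occur

    def test_single_passing_frame(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 3.0)
        mask = classify_trajectory(model, Trajectory(structure, frame[None]))
        assert mask.flags.tolist() == [True]

    def test_identical_frames_constant_mask(self, aneh_complex):
        structure, model = aneh_complex
        frame = _place_pair_at(structure, model, 3.0)
        mask = classify_trajectory(model, Trajectory(structure, np.tile(frame, (7, 1, 1))))
        assert mask.flags.all()

    def test_permutation_equivariance(self):
        top, model, frames = random_geometry_case(seed=5, n_frames=200)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(frames))
        base = classify_trajectory(model, Trajectory(top, frames)).flags
        permuted = classify_trajectory(model, Trajectory(top, frames[perm])).flags
        assert np.array_equal(permuted, base[perm])

    def test_threshold_monotonicity(self):
        """Raising an explicit distance threshold never loses active frames."""
        top, model, frames = random_geometry_case(seed=23, n_frames=300)
        traj = Trajectory(top, frames)
        counts = []
        for bump in (0.0, 1.0, 3.0):
            crits = tuple(
                DistanceCriterion(
                    a=c.a, b=c.b, threshold_mode="explicit",
                    threshold=(c.threshold or 3.22) + bump, label=c.label,
                )
                for c in model.distance_criteria
            )
            bumped = NACModel(model.name, crits, model.angle_criteria)
            counts.append(int(classify_trajectory(bumped, traj).flags.sum()))
        assert counts == sorted(counts)

    def test_conjunction_dominance(self):
        """Adding a criterion never increases the active count."""
        top, model, frames = random_geometry_case(seed=31, n_frames=300)
        traj = Trajectory(top, frames)
        full = int(classify_trajectory(model, traj).flags.sum())
        reduced = NACModel(
            model.name, model.distance_criteria[:1], angle_criteria=()
        )
        assert int(classify_trajectory(reduced, traj).flags.sum()) >= full


class TestFilterPoses:
    def test_construct_and_count(self, aneh_complex):
        """Of 32 synthetic docked poses, exactly the 7 built active survive."""
        structure, model = aneh_complex
        from nacscreen.sampler import SyntheticSpec, synth_trajectory

        spec = SyntheticSpec(
            topology=structure, model=model, n_frames=32,
            active_fraction=7 / 32, jitter=0.05, seed=9,
        )
        poses = synth_trajectory(spec)
        kept = filter_poses(model, poses)
        assert len(kept) == 7
        # original order preserved
        active_idx = [i for i, lab in enumerate(poses.frame_labels) if lab == "active"]
        assert np.allclose(kept.frames, poses.frames[active_idx])

    def test_all_fail_is_empty_with_warning(self, aneh_complex, caplog):
        structure, model = aneh_complex
        from nacscreen.sampler import SyntheticSpec, synth_trajectory

        poses = synth_trajectory(
            SyntheticSpec(
                topology=structure, model=model, n_frames=5,
                active_fraction=0.0, jitter=0.05, seed=2,
            )
        )
        with caplog.at_level("WARNING", logger="nacscreen.model"):
            kept = filter_poses(model, poses)
        assert len(kept) == 0
        assert any("no pose" in r.message for r in caplog.records)

    def test_all_pass_is_identity(self, aneh_complex):
        structure, model = aneh_complex
        from nacscreen.sampler import SyntheticSpec, synth_trajectory

        poses = synth_trajectory(
            SyntheticSpec(
                topology=structure, model=model, n_frames=5,
                active_fraction=1.0, jitter=0.05, seed=2,
            )
        )
        kept = filter_poses(model, poses)
        assert np.array_equal(kept.frames, poses.frames)


def test_active_mask_length_matches_trajectory(aneh_complex):
    structure, model = aneh_complex
    from nacscreen.sampler import SyntheticSpec, synth_trajectory

    traj = synth_trajectory(
        SyntheticSpec(
            topology=structure, model=model, n_frames=17,
            active_fraction=0.4, jitter=0.02, seed=1,
        )
    )
    mask = classify_trajectory(model, traj)
    assert len(mask) == len(traj)
    assert isinstance(mask, ActiveMask)
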