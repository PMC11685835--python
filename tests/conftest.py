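import numpy as np
import pytest

from nacscreen.fixtures import (
    aneh_like_complex,
    make_complex,
    make_peptide,
    make_pocket,
    pocket_nac_model,
)


@pytest.fixture(scope="session")
def aneh_complex():
    """Epoxide-hydrolase-style complex and its 3-criterion NAC model."""
    return aneh_like_complex()


@pytest.fixture(scope="session")
def small_peptide():
    return make_peptide({1: "A", 2: "G", 3: "L", 4: "S", 5: "V"})


@pytest.fixture(scope="session")
def small_complex():
    """5-residue peptide with an epoxide ligand near residue 3."""
    return make_complex({1: "A", 2: "G", 3: "L", 4: "S", 5: "V"}, ligand_near=3)


@pytest.fixture()
def pocket():
    return make_pocket()


@pytest.fixture()
def pocket_model():
    return pocket_nac_model(4.0)


# ---------------------------------------------------------------------------
# Independent geometry oracle, shared by oracle-equivalence tests.  Pure
# python/math over raw coordinates; deliberately does not reuse package
# geometry code.


def brute_force_active(model, topology, frames):
    """Recompute the per-frame active mask from scratch."""
    import math

    def find(sel):
        hits = [
            i
            for i, a in enumerate(topology.atoms)
            if a.resid == sel.resid
            and a.name == sel.atom_name
            and (sel.chain is None or a.chain == sel.chain)
            and (sel.entity is None
                 or (sel.entity == "ligand") == a.hetero)
        ]
        assert len(hits) == 1
        return hits[0]

    radii = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
             "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
             "SE": 1.90}
    flags = []
    for frame in frames:
        ok = True
        for c in model.distance_criteria:
            i, j = find(c.a), find(c.b)
            d = math.dist(tuple(frame[i]), tuple(frame[j]))
            if c.threshold_mode == "explicit":
                thr = c.threshold
            else:
                thr = radii[topology.atoms[i].element] + radii[topology.atoms[j].element]
            if not d < thr:
                ok = False
        for c in model.angle_criteria:
            i, j, k = find(c.a), find(c.vertex), find(c.c)
            u = [frame[i][x] - frame[j][x] for x in range(3)]
            v = [frame[k][x] - frame[j][x] for x in range(3)]
            dot = sum(a * b for a, b in zip(u, v))
            nu = math.sqrt(sum(a * a for a in u))
            nv = math.sqrt(sum(a * a for a in v))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (nu * nv)))))
            if not abs(ang - c.target_deg) <= c.tolerance_deg:
                ok = False
        flags.append(ok)
    return np.array(flags, dtype=bool)
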