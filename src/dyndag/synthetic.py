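"""Synthetic five-wave binary symptom cohorts from a known ground-truth DBN.

The generator emulates the statistical shape of a large naturalistic
schizophrenia outpatient cohort: ~1200 participants, 12 binary symptom
indicators, five waves at uniform spacing, and monotone loss to follow-up
down to ~810 by wave 5.  Data are produced by the exact process the
analysis assumes — a stationary first-order DBN whose within-slice graph
and transition kernel do not change over time — so downstream structure
and effect recovery can be scored against a known truth.

Conditional probability tables are additive in the parents:
``P(child = 1 | pa) = base + sum_j c_j * pa_j`` with every coefficient
magnitude at least ``effect_floor`` and the base chosen so all entries
stay inside [0.02, 0.98].  Under this parameterisation the contrast of
each parent (the change in the child's success probability when that
parent flips, all else fixed) equals ``|c_j|`` exactly in every
configuration.  Self-edge (momentum) coefficients are always positive;
other signs are random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import BinaryPanel, ItemSpec, DEFAULT_ITEMS, ConfigurationError
from .structures import DbnStructure, topological_order

#: Probability bounds for generated CPT entries.
_P_LO, _P_HI = 0.02, 0.98


@dataclass(frozen=True)
class AttritionSchedule:
    """Per-wave retention probabilities with monotone (absorbing) dropout.

    ``retention[w]`` is the probability that a participant observed at
    wave ``w`` (1-based, so index 0 is wave 1) is still observed at that
    wave given they were observed at the previous one.  Once lost, a
    participant never reappears.
    """

    retention: tuple[float, ...]

    def __post_init__(self):
        if any(not (0.0 <= r <= 1.0) for r in self.retention):
            raise ConfigurationError("retention probabilities must be in [0, 1]")

    def for_waves(self, n_waves: int) -> np.ndarray:
        r = list(self.retention)
        if len(r) < n_waves:
            r = r + [r[-1]] * (n_waves - len(r))
        return np.asarray(r[:n_waves], dtype=float)


#: Calibrated so a 1208-participant cohort retains ~810 by wave 5
#: (1208 * 0.905**4 ~ 811).
DEFAULT_ATTRITION = AttritionSchedule((1.0, 0.905, 0.905, 0.905, 0.905))

#: No dropout at any wave.
NO_ATTRITION = AttritionSchedule((1.0,))


@dataclass
class GroundTruth:
    """A DBN structure plus its generating CPTs.

    ``cpt_first[j]``: success probabilities of node ``j`` at wave 1 given
    its within-slice parents, indexed by the parent configuration integer
    (sorted parent order, first parent = least significant bit).

    ``cpt_trans[j]``: success probabilities of node ``j`` at wave ``t+1``
    given its within-slice parents (values at ``t+1``, low bits) followed
    by its between-slice parents (values at ``t``, high bits).
    """

    structure: DbnStructure
    cpt_first: list[np.ndarray]
    cpt_trans: list[np.ndarray]
    var_names: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        n = self.structure.n
        if not self.var_names:
            self.var_names = [f"V{j + 1}" for j in range(n)]
        for j in range(n):
            k1 = len(self.structure.w_parents(j))
            kt = k1 + len(self.structure.b_parents(j))
            for cpt, k, tag in ((self.cpt_first[j], k1, "first"),
                                (self.cpt_trans[j], kt, "transition")):
                cpt = np.asarray(cpt, dtype=float)
                if cpt.shape != (1 << k,):
                    raise ConfigurationError(
                        f"{tag} CPT of node {j} must have 2^{k} rows")
                if ((cpt < 0) | (cpt > 1)).any():
                    raise ConfigurationError("CPT entries must be probabilities")

    # Each CPT row is Bernoulli: P(0) = 1 - P(1), so rows sum to 1 by
    # construction; invariants reduce to the shape/range checks above.

    def to_json(self, path) -> None:
        d = {
            "structure": self.structure.to_dict(),
            "cpt_first": [c.tolist() for c in self.cpt_first],
            "cpt_trans": [c.tolist() for c in self.cpt_trans],
            "var_names": self.var_names,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            structure=DbnStructure.from_dict(d["structure"]),
            cpt_first=[np.asarray(c, dtype=float) for c in d["cpt_first"]],
            cpt_trans=[np.asarray(c, dtype=float) for c in d["cpt_trans"]],
            var_names=d["var_names"],
            seed=d["seed"],
        )


def _additive_cpt(k: int, rng: np.random.Generator, effect_floor: float,
                  force_positive: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Additive CPT over ``k`` parents; returns (table, coefficients).

    Coefficient magnitudes are ``effect_floor + U(0, 0.25)``, scaled down
    only if their total exceeds the available probability range (in which
    case the floor guarantee is unattainable for this in-degree and the
    coefficients shrink proportionally).
    """
    span = _P_HI - _P_LO
    if k == 0:
        return np.array([rng.uniform(0.15, 0.55)]), np.zeros(0)
    mags = effect_floor + rng.uniform(0.0, 0.25, size=k)
    if mags.sum() > span:
        if k * effect_floor <= span:
            # shrink only the headroom above the floor
            excess = mags - effect_floor
            mags = effect_floor + excess * (span - k * effect_floor) / excess.sum()
        else:
            mags *= span / mags.sum()  # floor unattainable at this in-degree
    signs = np.where(rng.random(k) < 0.5, -1.0, 1.0)
    if force_positive is not None:
        signs[force_positive] = 1.0
    c = mags * signs
    lo = _P_LO - c[c < 0].sum()
    hi = max(_P_HI - c[c > 0].sum(), lo)  # interval can be ~0 wide after scaling
    base = rng.uniform(lo, hi)
    configs = (np.arange(1 << k)[:, None] >> np.arange(k)) & 1
    table = base + configs @ c
    return np.clip(table, _P_LO, _P_HI), c


def generate_true_dbn(n_vars: int = 12, within_density: float = 0.15,
                      between_density: float = 0.05, self_edge_prob: float = 0.9,
                      effect_floor: float = 0.3, seed: int | None = None,
                      var_names: list[str] | None = None) -> GroundTruth:
    """Draw a random ground-truth DBN.

    The within-slice DAG places an edge independently with probability
    ``within_density`` on each of the ``n (n - 1) / 2`` pairs ordered by a
    random permutation (so the expected edge count is density times the
    pair count).  Between-slice self-edges appear with probability
    ``self_edge_prob`` and carry positive coefficients (symptom momentum);
    off-diagonal between-slice edges appear with ``between_density``.
    """
    for name, v in (("within_density", within_density),
                    ("between_density", between_density),
                    ("self_edge_prob", self_edge_prob)):
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1]")
    if not (0.0 < effect_floor <= 1.0):
        raise ConfigurationError("effect_floor must be in (0, 1]")
    if n_vars < 2:
        raise ConfigurationError("n_vars must be at least 2")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_vars)
    W = np.zeros((n_vars, n_vars), dtype=bool)
    for a in range(n_vars):
        for b in range(a + 1, n_vars):
            if rng.random() < within_density:
                W[order[a], order[b]] = True
    # Between-slice parents are budgeted so each transition family keeps
    # enough probability range to honour the contrast floor: the self-edge
    # is drawn unconditionally, further sources only while the total
    # in-degree stays within floor(range / effect_floor).
    k_max = max(1, int((_P_HI - _P_LO) / effect_floor))
    B = np.zeros((n_vars, n_vars), dtype=bool)
    np.fill_diagonal(B, rng.random(n_vars) < self_edge_prob)
    for j in range(n_vars):
        indeg = int(W[:, j].sum() + B[j, j])
        for i in rng.permutation(n_vars):
            if i == j:
                continue
            if indeg >= k_max:
                break
            if rng.random() < between_density:
                B[i, j] = True
                indeg += 1
    structure = DbnStructure(W, B)

    cpt_first, cpt_trans = [], []
    for j in range(n_vars):
        wpa = structure.w_parents(j)
        bpa = structure.b_parents(j)
        tab1, _ = _additive_cpt(len(wpa), rng, effect_floor)
        # transition parents: W-parents (low bits) then B-parents; the
        # self-edge, when present, gets a positive momentum coefficient
        force = None
        if j in bpa:
            force = np.zeros(len(wpa) + len(bpa), dtype=bool)
            force[len(wpa) + int(np.searchsorted(bpa, j))] = True
        tabt, _ = _additive_cpt(len(wpa) + len(bpa), rng, effect_floor,
                                force_positive=force)
        cpt_first.append(tab1)
        cpt_trans.append(tabt)

    names = list(var_names) if var_names else [it.name for it in DEFAULT_ITEMS[:n_vars]]
    if len(names) < n_vars:
        names += [f"V{j + 1}" for j in range(len(names), n_vars)]
    return GroundTruth(structure=structure, cpt_first=cpt_first,
                       cpt_trans=cpt_trans, var_names=names, seed=seed)


def simulate_cohort(truth: GroundTruth, n_participants: int = 1208,
                    n_waves: int = 5,
                    attrition: AttritionSchedule = DEFAULT_ATTRITION,
                    seed: int | None = None) -> BinaryPanel:
    """Simulate a binary symptom panel from a ground-truth DBN.

    Wave 1 is drawn from the within-slice model; every later wave from the
    stationary transition CPTs given the previous wave.  Dropout is
    missing completely at random at the interview level and monotone:
    a participant lost at wave ``w`` is missing at all later waves.
    """
    if n_waves < 2:
        raise ConfigurationError("n_waves must be at least 2")
    rng = np.random.default_rng(seed)
    st = truth.structure
    n = st.n
    order = topological_order(st.within)

    values = np.zeros((n_participants, n_waves, n), dtype=np.uint8)
    # wave 1: within-slice model
    for j in order:
        wpa = st.w_parents(j)
        idx = values[:, 0, wpa] @ (1 << np.arange(len(wpa)))
        p = truth.cpt_first[j][idx]
        values[:, 0, j] = rng.random(n_participants) < p
    # subsequent waves: stationary transition kernel
    for w in range(1, n_waves):
        for j in order:
            wpa = st.w_parents(j)
            bpa = st.b_parents(j)
            idx = values[:, w, wpa] @ (1 << np.arange(len(wpa)))
            idx = idx + (values[:, w - 1, bpa] @ (1 << np.arange(len(bpa)))
                         << len(wpa))
            p = truth.cpt_trans[j][idx]
            values[:, w, j] = rng.random(n_participants) < p

    # monotone MCAR dropout at the interview level
    ret = attrition.for_waves(n_waves)
    present = np.ones((n_participants, n_waves), dtype=bool)
    for w in range(n_waves):
        stay = rng.random(n_participants) < ret[w]
        present[:, w] = (present[:, w - 1] if w else True) & stay
    out = values.astype(float)
    out[~present] = np.nan

    width = len(str(n_participants))
    parts = [f"S{i + 1:0{width}d}" for i in range(n_participants)]
    idx = pd.MultiIndex.from_product([parts, range(1, n_waves + 1)],
                                     names=["participant", "wave"])
    df = pd.DataFrame(out.reshape(n_participants * n_waves, n),
                      index=idx, columns=truth.var_names)
    items = tuple(ItemSpec(v, "SIM", 0, 1) for v in truth.var_names)
    return BinaryPanel(items=items, values=df)
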