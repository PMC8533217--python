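"""Ground-truth-labeled synthetic trajectories for pipeline validation.

The production MD trajectories behind the published statistics are not
deposited, so this module generates toy trajectories that emulate their
statistical structure: a two-state (kinked / open) Markov chain drives the
Gln147-Trp153 and Gln147-Thr261 hydrogen-bond distances (state-dependent
Gaussian spreads) and the ligand C8-C9-C10-C11 torsion χ (state-dependent
von Mises mixture over the −60° and 180° modes), so that χ's actionable
probability is correlated with the distance state.

The embedding is geometrically, not physically, faithful: each distance pair
is placed along a fixed axis in a well-separated spatial block, and the
dihedral quad is built from internal coordinates (C-C bonds 1.53 Å, angles
111°).  There is no force field, membrane, or water — only the observables'
joint distribution is emulated.  Measuring d1, d2, χ from the emitted
coordinates reproduces the sampled values to ~1e-6.

Preset models anchor their basin locations to the published landscape
coordinates (e.g. substrate kinked minimum at Gln147-Trp153 = 2.0 Å,
Gln147-Thr261 = 2.2 Å; product secondary subpopulation near 4.1/5.6 Å) as
emulation targets, not as claims about MD kinetics; transition probabilities
are chosen for statistical test power (fast-mixing chains).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StructureError
from .geometry import place_fourth_atom
from .trajio import (
    AtomRecord, AtomSpec, Frame, Topology, Trajectory,
    write_structure, write_trajectory,
)

STATES = ("kinked", "open")

#: Internal coordinates of the embedded C8-C9-C10-C11 quad.
_BOND = 1.53     # Å
_ANGLE = 111.0   # degrees

#: Default atom addresses of the toy system (PDB v3 names).
D1_PAIR = (AtomSpec(147, "OE1"), AtomSpec(153, "HE1"))   # Gln147–Trp153
D2_PAIR = (AtomSpec(147, "HE22"), AtomSpec(261, "OG1"))  # Gln147–Thr261
CHI_QUAD = (AtomSpec(501, "C8"), AtomSpec(501, "C9"),
            AtomSpec(501, "C10"), AtomSpec(501, "C11"))
POCKET_CENTER = AtomSpec(501, "C5")


@dataclass(frozen=True)
class GaussianParams:
    mean: float  # Å
    sd: float    # Å

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("standard deviation must be positive")


@dataclass(frozen=True)
class ChiMixture:
    """Circular mixture over torsion modes: centers (deg), von Mises
    concentrations, and weights summing to 1."""

    centers: tuple[float, ...]
    kappas: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if any(k <= 0 for k in self.kappas):
            raise ValueError("concentrations must be positive")

    def window_probability(self, center: float = -60.0, tolerance: float = 5.0) -> float:
        """P(|χ − center| ≤ tolerance on the circle) under the mixture."""
        total = 0.0
        for mu, kappa, w in zip(self.centers, self.kappas, self.weights):
            delta = (center - mu + 180.0) % 360.0 - 180.0
            lo, hi = np.radians(delta - tolerance), np.radians(delta + tolerance)
            # split windows that wrap past ±180° relative to the component
            segs = []
            if lo < -np.pi:
                segs += [(-np.pi, hi), (2 * np.pi + lo, np.pi)]
            elif hi > np.pi:
                segs += [(lo, np.pi), (-np.pi, hi - 2 * np.pi)]
            else:
                segs = [(lo, hi)]
            for a, b in segs:
                total += w * (stats.vonmises.cdf(b, kappa) -
                              stats.vonmises.cdf(a, kappa))
        return float(total)


@dataclass
class TwoStateModel:
    """Generative parameters of the kinked/open toy trajectory."""

    transition_matrix: np.ndarray  # 2×2 row-stochastic, order (kinked, open)
    d1_params: Optional[dict[str, GaussianParams]]
    d2_params: Optional[dict[str, GaussianParams]]
    chi_params: dict[str, ChiMixture]
    seed: Optional[int] = None

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.shape != (2, 2) or not np.allclose(T.sum(axis=1), 1.0) or np.any(T < 0):
            raise ValueError("transition matrix must be 2x2 row-stochastic")
        self.transition_matrix = T
        has_d1 = self.d1_params is not None
        if has_d1 != (self.d2_params is not None):
            raise ValueError("d1_params and d2_params must both be set or both None")

    @property
    def has_distances(self) -> bool:
        return self.d1_params is not None

    def stationary(self) -> np.ndarray:
        """Stationary distribution (π_kinked, π_open) of the chain."""
        a = self.transition_matrix[0, 1]  # kinked -> open
        b = self.transition_matrix[1, 0]  # open -> kinked
        if a + b == 0:
            return np.array([0.5, 0.5])
        return np.array([b / (a + b), a / (a + b)])

    def mixing_lambda(self) -> float:
        """Second eigenvalue 1 − (a + b); controls frame autocorrelation."""
        return 1.0 - self.transition_matrix[0, 1] - self.transition_matrix[1, 0]

    def actionable_probability(self, state: str, tolerance: float = 5.0) -> float:
        """True P(χ within tolerance of −60°) in the given state."""
        return self.chi_params[state].window_probability(-60.0, tolerance)

    def hbond_probability(self, state: str, cutoff: float = 2.5) -> float:
        """True P(d1 ≤ cutoff and d2 ≤ cutoff) in the given state (the two
        distances are conditionally independent given the state)."""
        if not self.has_distances:
            raise ValueError("model has no distance emissions")
        p = 1.0
        for params in (self.d1_params[state], self.d2_params[state]):
            p *= stats.norm.cdf(cutoff, loc=params.mean, scale=params.sd)
        return float(p)

    def conditional_actionable_truth(self, cutoff: float = 2.5,
                                     tolerance: float = 5.0
                                     ) -> tuple[float, float]:
        """True (P(actionable | hydrogen-bonded), P(actionable | not)).

        The hydrogen-bond indicator is not identical to the hidden state:
        each state contributes to both conditioning classes according to its
        Gaussian tail mass past the cutoff, so the truth follows from Bayes
        over the stationary state weights.
        """
        pi = self.stationary()
        num_b = num_u = den_b = den_u = 0.0
        for w, state in zip(pi, STATES):
            pb = self.hbond_probability(state, cutoff)
            pa = self.actionable_probability(state, tolerance)
            num_b += w * pb * pa
            den_b += w * pb
            num_u += w * (1 - pb) * pa
            den_u += w * (1 - pb)
        return num_b / den_b, num_u / den_u

    def occupancy_standard_error(self, n_frames: int) -> float:
        """Standard error of the empirical kinked occupancy over ``n_frames``.

        Markov-chain frames are autocorrelated, so the binomial variance is
        inflated by (1+λ)/(1−λ) with λ the chain's second eigenvalue.
        """
        p = self.stationary()[0]
        lam = self.mixing_lambda()
        return float(np.sqrt(p * (1 - p) / n_frames * (1 + lam) / (1 - lam)))

    def to_dict(self) -> dict:
        def gp(d):
            return None if d is None else {
                s: {"mean": p.mean, "sd": p.sd} for s, p in d.items()}
        return {
            "transition_matrix": self.transition_matrix.tolist(),
            "d1_params": gp(self.d1_params),
            "d2_params": gp(self.d2_params),
            "chi_params": {
                s: {"centers": list(m.centers), "kappas": list(m.kappas),
                    "weights": list(m.weights)}
                for s, m in self.chi_params.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStateModel":
        def gp(entry):
            return None if entry is None else {
                s: GaussianParams(**p) for s, p in entry.items()}
        return cls(
            transition_matrix=np.array(d["transition_matrix"]),
            d1_params=gp(d["d1_params"]),
            d2_params=gp(d["d2_params"]),
            chi_params={s: ChiMixture(tuple(m["centers"]), tuple(m["kappas"]),
                                      tuple(m["weights"]))
                        for s, m in d["chi_params"].items()},
            seed=d.get("seed"),
        )


@dataclass
class LabeledTrajectory:
    trajectory: Trajectory
    state_labels: np.ndarray        # per-frame "kinked"/"open"
    d1: Optional[np.ndarray]        # emitted observables (None for waterbox)
    d2: Optional[np.ndarray]
    chi: np.ndarray
    model: TwoStateModel


_KAPPA_GAUCHE = 30.0
_KAPPA_TRANS = 10.0


def _chi_mixture_for(actionable_target: float, tolerance: float = 5.0) -> ChiMixture:
    """Solve the gauche-component weight so that the mixture's probability of
    being within ``tolerance`` of −60° equals ``actionable_target``."""
    p_g = ChiMixture((-60.0,), (_KAPPA_GAUCHE,), (1.0,)).window_probability(
        -60.0, tolerance)
    p_t = ChiMixture((180.0,), (_KAPPA_TRANS,), (1.0,)).window_probability(
        -60.0, tolerance)
    w = (actionable_target - p_t) / (p_g - p_t)
    if not 0.0 < w < 1.0:
        raise ValueError(
            f"actionable target {actionable_target} unreachable with the "
            f"default concentrations")
    return ChiMixture((-60.0, 180.0), (_KAPPA_GAUCHE, _KAPPA_TRANS), (w, 1.0 - w))


def _transition(kinked_occupancy: float, rate_sum: float = 0.8) -> np.ndarray:
    """Row-stochastic matrix with the requested stationary kinked occupancy
    and a + b = rate_sum (λ = 1 − rate_sum; fast mixing for test power)."""
    a = rate_sum * (1.0 - kinked_occupancy)  # kinked -> open
    b = rate_sum * kinked_occupancy          # open -> kinked
    return np.array([[1.0 - a, a], [b, 1.0 - b]])


def presets() -> dict[str, TwoStateModel]:
    """Named generative models emulating the four ligand-state systems.

    Basin means anchor to the published landscape coordinates; conditional
    actionable probabilities for the substrate preset are calibrated to
    0.18 (kinked) / 0.035 (open), mirroring the reported contrast.
    """
    def gauss(km, ks, om, os):
        return {"kinked": GaussianParams(km, ks), "open": GaussianParams(om, os)}

    return {
        "substrate": TwoStateModel(
            transition_matrix=_transition(0.9),
            d1_params=gauss(2.0, 0.15, 4.1, 0.15),
            d2_params=gauss(2.2, 0.15, 5.6, 0.15),
            chi_params={"kinked": _chi_mixture_for(0.18),
                        "open": _chi_mixture_for(0.035)},
        ),
        "product": TwoStateModel(
            transition_matrix=_transition(0.4),
            d1_params=gauss(2.0, 0.15, 4.1, 0.20),
            d2_params=gauss(2.3, 0.15, 5.6, 0.20),
            chi_params={"kinked": _chi_mixture_for(0.10),
                        "open": _chi_mixture_for(0.03)},
        ),
        "apoprotein": TwoStateModel(
            transition_matrix=_transition(0.45),
            d1_params=gauss(1.9, 0.15, 2.0, 0.20),
            d2_params=gauss(2.2, 0.15, 4.3, 0.20),
            chi_params={"kinked": _chi_mixture_for(0.12),
                        "open": _chi_mixture_for(0.04)},
        ),
        "coa": TwoStateModel(
            transition_matrix=_transition(0.4),
            d1_params=gauss(2.0, 0.15, 1.9, 0.20),
            d2_params=gauss(2.3, 0.15, 4.9, 0.20),
            chi_params={"kinked": _chi_mixture_for(0.12),
                        "open": _chi_mixture_for(0.04)},
        ),
        "waterbox": TwoStateModel(
            transition_matrix=np.array([[0.5, 0.5], [0.5, 0.5]]),
            d1_params=None,
            d2_params=None,
            chi_params={"kinked": _chi_mixture_for(0.03),
                        "open": _chi_mixture_for(0.03)},
        ),
    }


def get_preset(name: str) -> TwoStateModel:
    try:
        return presets()[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets())}") from None


def toy_topology(with_protein: bool = True) -> Topology:
    """Minimal topology carrying exactly the atoms the measurements address."""
    atoms = []
    serial = 1

    def add(name, res_name, res_num, element):
        nonlocal serial
        atoms.append(AtomRecord(serial=serial, atom_name=name,
                                residue_name=res_name, residue_number=res_num,
                                chain_id="A", element=element))
        serial += 1

    if with_protein:
        add("OE1", "GLN", 147, "O")
        add("HE22", "GLN", 147, "H")
        add("HE1", "TRP", 153, "H")
        add("OG1", "THR", 261, "O")
    for name in ("C5", "C8", "C9", "C10", "C11"):
        add(name, "STC", 501, "C")
    return Topology(atoms)


# fixed spatial blocks of the toy embedding (Å)
_BLOCK_D2 = np.array([0.0, 50.0, 0.0])
_BLOCK_LIG = np.array([0.0, 0.0, 50.0])


def _quad_base() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed C8, C9, C10 positions of the embedded torsion quad."""
    c8 = _BLOCK_LIG
    c9 = c8 + np.array([_BOND, 0.0, 0.0])
    theta = np.radians(_ANGLE)
    c10 = c9 + _BOND * np.array([-np.cos(theta), np.sin(theta), 0.0])
    return c8, c9, c10


def simulate(model: TwoStateModel, n_frames: int,
             seed: Optional[int] = None) -> LabeledTrajectory:
    """Sample a labeled toy trajectory from the generative model.

    The state sequence starts from the chain's stationary distribution;
    observables are drawn per state and embedded into coordinates so that
    measuring them back reproduces the sampled values.  Deterministic for a
    fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)

    T = model.transition_matrix
    pi = model.stationary()
    states = np.empty(n_frames, dtype=np.int8)
    u = rng.random(n_frames)
    states[0] = 0 if u[0] < pi[0] else 1
    for t in range(1, n_frames):
        states[t] = 0 if u[t] < T[states[t - 1], 0] else 1
    labels = np.array(STATES)[states]

    def draw_gauss(params):
        means = np.array([params[s].mean for s in STATES])[states]
        sds = np.array([params[s].sd for s in STATES])[states]
        vals = rng.normal(means, sds)
        return np.maximum(vals, 0.1)  # distances stay physical

    d1 = draw_gauss(model.d1_params) if model.has_distances else None
    d2 = draw_gauss(model.d2_params) if model.has_distances else None

    chi = np.empty(n_frames)
    for si, s in enumerate(STATES):
        mask = states == si
        n = int(mask.sum())
        if n == 0:
            continue
        mix = model.chi_params[s]
        comp = rng.choice(len(mix.weights), size=n, p=mix.weights)
        centers = np.radians(np.array(mix.centers))[comp]
        kappas = np.array(mix.kappas)[comp]
        chi[mask] = np.degrees(rng.vonmises(centers, kappas))
    chi = np.where(chi <= -180.0, chi + 360.0, chi)

    topology = toy_topology(with_protein=model.has_distances)
    coords = np.zeros((n_frames, topology.n_atoms, 3))
    c8, c9, c10 = _quad_base()
    c11 = place_fourth_atom(c8, c9, c10, _BOND, _ANGLE, chi)
    offset = 0
    if model.has_distances:
        # OE1 fixed at origin, HE1 along +x at distance d1
        coords[:, 0] = 0.0
        coords[:, 2, 0] = d1
        # HE22 fixed in a distant block, OG1 along +y at distance d2
        coords[:, 1] = _BLOCK_D2
        coords[:, 3] = _BLOCK_D2
        coords[:, 3, 1] += d2
        offset = 4
    coords[:, offset + 0] = c8 + np.array([-2.5, 0.0, 0.0])  # C5 near the quad
    coords[:, offset + 1] = c8
    coords[:, offset + 2] = c9
    coords[:, offset + 3] = c10
    coords[:, offset + 4] = c11

    frames = [Frame(index=i, coords=coords[i]) for i in range(n_frames)]
    traj = Trajectory(topology, frames, replicate_id=f"synthetic-{seed}")
    return LabeledTrajectory(trajectory=traj, state_labels=labels,
                             d1=d1, d2=d2, chi=chi, model=model)


def write_fixture(lt: LabeledTrajectory, directory,
                  frames_format: str = "dcd") -> dict[str, Path]:
    """Write a fixture bundle: topology.pdb, frames.(dcd|pdb), labels.csv,
    model.json.  Readable back with :mod:`scdtraj.trajio`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    traj = lt.trajectory

    top_path = directory / "topology.pdb"
    write_structure(Trajectory(traj.topology, [traj.frames[0]],
                               traj.replicate_id), top_path)
    frames_path = directory / f"frames.{frames_format}"
    write_trajectory(traj, frames_path, frames_format)

    labels_path = directory / "labels.csv"
    table = {"frame": np.arange(traj.n_frames), "state": lt.state_labels}
    if lt.d1 is not None:
        table["d1"] = lt.d1
        table["d2"] = lt.d2
    table["chi"] = lt.chi
    pd.DataFrame(table).to_csv(labels_path, index=False, float_format="%.6f")

    model_path = directory / "model.json"
    with open(model_path, "w") as fh:
        json.dump(lt.model.to_dict(), fh, indent=1)
    return {"topology": top_path, "frames": frames_path,
            "labels": labels_path, "model": model_path}


def crystal_fragment_standin() -> Trajectory:
    """Synthetic stand-in for the crystal-structure fragment used in geometry
    validation (the real entry is a network download this package does not
    require).  It embeds the published active-site geometry by direct
    coordinate construction: two iron ions 6.8 Å apart and a four-carbon
    stearoyl fragment whose C8-C9-C10-C11 torsion is −111.1°.
    """
    atoms = [
        AtomRecord(1, "FE", "FE", 601, "A", "FE"),
        AtomRecord(2, "FE", "FE", 602, "A", "FE"),
    ]
    fe1 = np.array([10.0, 10.0, 10.0])
    fe2 = fe1 + np.array([0.0, 0.0, 6.8])

    c8 = np.array([20.0, 10.0, 10.0])
    c9 = c8 + np.array([_BOND, 0.0, 0.0])
    theta = np.radians(_ANGLE)
    c10 = c9 + _BOND * np.array([-np.cos(theta), np.sin(theta), 0.0])
    c11 = place_fourth_atom(c8, c9, c10, _BOND, _ANGLE, -111.1)
    for i, name in enumerate(("C8", "C9", "C10", "C11")):
        atoms.append(AtomRecord(3 + i, name, "STC", 700, "A", "C"))

    coords = np.vstack([fe1, fe2, c8, c9, c10, c11])
    return Trajectory(Topology(atoms), [Frame(0, coords)],
                      replicate_id="synthetic-crystal-fragment")
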