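"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the shape of a small-molecule anisotropic-NMR study
without any quantum chemistry: a tetrahedral hydrocarbon with two
stereocenters and one or two rotatable substituent chains stands in for
the DFT conformer ensembles; shielding tensors are drawn with realistic
anisotropies (tens to hundreds of ppm); a dimensionless alignment tensor
of magnitude ~1e-4..1e-3 produces one-bond C–H RDCs and ¹³C RCSAs through
the exact back-calculation used in fitting, plus seeded Gaussian noise;
and a "wrong diastereomer" decoy is built by inverting one stereocenter.

Everything is a pure function of its parameters and seed, so any dataset
can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import AnisofitError, ValidationError
from .records import (
    EXTERNAL,
    Conformer,
    ConformationalEnsemble,
    RCSADatum,
    RDCDatum,
    ShieldingTensor,
    ShiftDatum,
    shielding_map,
)
from .tensor import AlignmentTensor, DipolarPair, back_calc_rcsa, rdc_coefficients
from .thermo import PopulationSet

__all__ = [
    "NoiseModel",
    "SyntheticTruth",
    "SimulatedData",
    "make_toy_ensemble",
    "make_true_tensor",
    "make_shieldings",
    "simulate_dataset",
    "make_decoy_configuration",
    "perturb_computed_shifts",
]

CC_BOND = 1.53  # Å
CH_BOND = 1.09  # Å

_COVALENT_RADII = {"H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73, "S": 1.02, "F": 0.71}

# tetrahedral unit directions (diamond-lattice frame)
_T = 1.0 / np.sqrt(3.0)
_TET = np.array([
    [_T, _T, _T],
    [_T, -_T, -_T],
    [-_T, _T, -_T],
    [-_T, -_T, _T],
])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rotation matrix (via a normalized quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _axis_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about *axis* by *angle_deg* (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


@dataclass
class _ToyTemplate:
    labels: list[str]
    elements: list[str]
    coords: np.ndarray
    chain_a_axis: tuple[int, int]  # (fixed atom index, pivot atom index)
    chain_a_atoms: list[int]  # indices rotated by the chain-A dihedral
    chain_b_axis: tuple[int, int]
    chain_b_atoms: list[int]


def _build_template(n_atoms: int) -> _ToyTemplate:
    """Tetrahedral two-stereocenter hydrocarbon on a diamond-lattice frame.

    Skeleton: C1(H)(CH3)(chain A) – C2(H)(CH3)(ethyl).  Chain A has a
    variable number of carbons so the total atom count approximates
    *n_atoms*; chain A (about C1→C4) and the ethyl (about C2→C_b) are the
    rotatable substituents.
    """
    if not (10 <= n_atoms <= 60):
        raise ValidationError(f"n_atoms must be in [10, 60], got {n_atoms}")
    m = max(1, round((n_atoms - 20) / 3))  # chain-A carbon count

    labels: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []

    def add(label: str, element: str, pos: np.ndarray) -> int:
        labels.append(label)
        elements.append(element)
        coords.append(pos)
        return len(labels) - 1

    c_count = 0

    def next_c() -> str:
        nonlocal c_count
        c_count += 1
        return f"C{c_count}"

    # stereocenter 1 at origin, bonds along +TET; stereocenter 2 along dir 0
    c1 = add(next_c(), "C", np.zeros(3))
    c2 = add(next_c(), "C", _TET[0] * CC_BOND)
    add("H1", "H", _TET[1] * CH_BOND)  # H on C1
    # methyl on C1 (dir 2); its own bonds use the -TET set
    me1 = next_c()
    me1_pos = _TET[2] * CC_BOND
    add(me1, "C", me1_pos)
    for j, d in enumerate((0, 1, 3)):
        add(f"H{me1[1:]}{'abc'[j]}", "H", me1_pos - _TET[d] * CH_BOND)

    # chain A off C1 (dir 3), alternating lattice directions 1 and 3
    # (alternating 2 and 3 would clash with the methyl on the second
    # stereocenter, which sits along direction 2)
    chain_a_atoms: list[int] = []
    pos = _TET[3] * CC_BOND
    sign = -1.0
    back_dir, fwd_dir = 3, 1
    pivot_a = None
    for i in range(m):
        lab = next_c()
        idx = add(lab, "C", pos)
        if i == 0:
            pivot_a = idx
        else:
            chain_a_atoms.append(idx)
        terminal = i == m - 1
        h_dirs = [d for d in range(4) if d not in (back_dir, fwd_dir)] if not terminal \
            else [d for d in range(4) if d != back_dir]
        for j, d in enumerate(h_dirs):
            chain_a_atoms.append(
                add(f"H{lab[1:]}{'abc'[j]}", "H", pos + sign * _TET[d] * CH_BOND)
            )
        if not terminal:
            pos = pos + sign * _TET[fwd_dir] * CC_BOND
            sign = -sign
            back_dir, fwd_dir = fwd_dir, 4 - fwd_dir  # alternate 1 <-> 3

    # substituents on C2: bonds along -TET set
    c2_pos = _TET[0] * CC_BOND
    add("H2", "H", c2_pos - _TET[1] * CH_BOND)
    me2 = next_c()
    me2_pos = c2_pos - _TET[2] * CC_BOND
    add(me2, "C", me2_pos)
    for j, d in enumerate((0, 1, 3)):
        add(f"H{me2[1:]}{'abc'[j]}", "H", me2_pos + _TET[d] * CH_BOND)

    # ethyl chain B off C2 (dir 3)
    eb1 = next_c()
    eb1_pos = c2_pos - _TET[3] * CC_BOND
    eb1_idx = add(eb1, "C", eb1_pos)
    chain_b_atoms: list[int] = []
    for j, d in enumerate((1, 2)):
        chain_b_atoms.append(
            add(f"H{eb1[1:]}{'ab'[j]}", "H", eb1_pos + _TET[d] * CH_BOND)
        )
    eb2 = next_c()
    eb2_pos = eb1_pos + _TET[0] * CC_BOND
    chain_b_atoms.append(add(eb2, "C", eb2_pos))
    for j, d in enumerate((1, 2, 3)):
        chain_b_atoms.append(
            add(f"H{eb2[1:]}{'abc'[j]}", "H", eb2_pos - _TET[d] * CH_BOND)
        )

    xyz = np.array(coords)
    # pre-stagger chain A by 60° off the ideal lattice: on the pure diamond
    # lattice the substituents of the two stereocenters share 1,3 sites, so
    # a lattice-aligned chain collides with the inverted-center decoy
    origin = xyz[pivot_a]
    rot = _axis_rotation(xyz[pivot_a] - xyz[c1], 60.0)
    xyz[chain_a_atoms] = (xyz[chain_a_atoms] - origin) @ rot.T + origin

    return _ToyTemplate(
        labels=labels,
        elements=elements,
        coords=xyz,
        chain_a_axis=(c1, pivot_a),
        chain_a_atoms=chain_a_atoms,
        chain_b_axis=(c2, eb1_idx),
        chain_b_atoms=chain_b_atoms,
    )


def make_toy_ensemble(
    n_conformers: int,
    n_atoms: int = 29,
    dihedral_spec: dict[str, Sequence[float]] | None = None,
    seed: int = 0,
    configuration_label: str = "truth",
    jitter: float = 0.04,
) -> ConformationalEnsemble:
    """Deterministic toy conformer ensemble.

    Conformers share one jittered base geometry and differ only by rigid
    rotation of the chain-A (and optionally chain-B) substituent about its
    bond axis.  ``dihedral_spec`` maps ``"chain_a"``/``"chain_b"`` to one
    dihedral angle (degrees) per conformer; by default chain A is sampled
    evenly over 360°.  *jitter* (Å, seeded Gaussian on the base geometry)
    breaks the ideal lattice symmetry so bond directions span orientation
    space — without it all bonds lie along four directions and alignment
    fits are degenerate.
    """
    if n_conformers < 1:
        raise ValidationError("n_conformers must be >= 1")
    tmpl = _build_template(n_atoms)
    if dihedral_spec is None:
        # default chain-A rotamers sample the sterically open arc of the
        # rotation profile (the sector opposite it eclipses the methyl on
        # the second stereocenter, as a real conformer search would reject)
        dihedral_spec = {
            "chain_a": [-60.0 + 180.0 * i / n_conformers
                        for i in range(n_conformers)]
        }
    for key, angles in dihedral_spec.items():
        if key not in ("chain_a", "chain_b"):
            raise ValidationError(f"unknown rotatable substituent {key!r}")
        if len(angles) != n_conformers:
            raise ValidationError(
                f"dihedral_spec[{key!r}] must list {n_conformers} angles"
            )
    rng = np.random.default_rng(seed)
    base = tmpl.coords + rng.normal(0.0, jitter, size=tmpl.coords.shape)
    # topology is fixed by the template; derive it once from the (safe)
    # base geometry so rotated conformers can be checked for steric clashes
    base_conf = Conformer("base", tuple(tmpl.labels), tuple(tmpl.elements), base)
    base_adj = _bonds(base_conf)

    conformers = []
    for i in range(n_conformers):
        coords = base.copy()
        for key, (axis, atoms) in (
            ("chain_a", (tmpl.chain_a_axis, tmpl.chain_a_atoms)),
            ("chain_b", (tmpl.chain_b_axis, tmpl.chain_b_atoms)),
        ):
            if key not in dihedral_spec:
                continue
            origin = base[axis[1]]
            rot = _axis_rotation(base[axis[1]] - base[axis[0]],
                                 float(dihedral_spec[key][i]))
            coords[atoms] = (coords[atoms] - origin) @ rot.T + origin
        dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        for a in range(len(coords)):
            for b_ in range(a + 1, len(coords)):
                if b_ not in base_adj[a] and dist[a, b_] < 1.2:
                    raise ValidationError(
                        f"conformer {i + 1}: dihedral spec brings "
                        f"{tmpl.labels[a]!r} within {dist[a, b_]:.2f} Å of "
                        f"{tmpl.labels[b_]!r}; choose dihedrals outside the "
                        "sterically crowded sector"
                    )
        conformers.append(
            Conformer(
                conformer_id=f"c{i + 1}",
                atom_labels=tuple(tmpl.labels),
                elements=tuple(tmpl.elements),
                coords=coords,
            )
        )
    return ConformationalEnsemble(configuration_label, tuple(conformers))


def make_true_tensor(
    axial_magnitude: float = 5.0e-4,
    rhombicity: float = 0.3,
    orientation_seed: int = 0,
) -> AlignmentTensor:
    """Traceless symmetric tensor with prescribed eigenvalue structure.

    ``axial_magnitude`` is S_zz of the principal frame (typical weak
    alignment: 1e-4..1e-3); ``rhombicity`` is (S_xx − S_yy)/S_zz ∈ [0, 2/3].
    The principal frame is rotated uniformly at random per seed.
    """
    if not (1e-5 <= axial_magnitude <= 1e-2):
        raise ValidationError(
            f"axial_magnitude {axial_magnitude!r} outside [1e-5, 1e-2]"
        )
    if not (0.0 <= rhombicity <= 2.0 / 3.0):
        raise ValidationError(f"rhombicity {rhombicity!r} outside [0, 2/3]")
    szz = axial_magnitude
    sxx = 0.5 * (rhombicity - 1.0) * szz
    syy = -0.5 * (rhombicity + 1.0) * szz
    rot = _random_rotation(np.random.default_rng(orientation_seed))
    return AlignmentTensor.from_matrix(rot @ np.diag([sxx, syy, szz]) @ rot.T)


@dataclass(frozen=True)
class NoiseModel:
    """Per-block measurement noise (presets mirror good small-molecule data)."""

    sigma_rdc_hz: float = 0.5
    sigma_rcsa_ppb: float = 2.0
    sigma_c13_ppm: float = 0.2
    sigma_h1_ppm: float = 0.02
    relative: float | None = None  # overrides RDC/RCSA sigmas as frac × rms(clean)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    true_tensor: AlignmentTensor
    true_populations: PopulationSet
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    decoy_map: str | None = None

    def to_dict(self) -> dict:
        return {
            "true_tensor": self.true_tensor.to_vector().tolist(),
            "true_populations": dict(self.true_populations.weights),
            "temperature": self.true_populations.temperature,
            "noise": {
                "sigma_rdc_hz": self.noise.sigma_rdc_hz,
                "sigma_rcsa_ppb": self.noise.sigma_rcsa_ppb,
                "sigma_c13_ppm": self.noise.sigma_c13_ppm,
                "sigma_h1_ppm": self.noise.sigma_h1_ppm,
                "relative": self.noise.relative,
            },
            "seed": self.seed,
            "decoy_map": self.decoy_map,
        }


@dataclass
class SimulatedData:
    """One generated dataset bundle."""

    rdcs: list[RDCDatum]
    rcsas: list[RCSADatum]
    shifts: list[ShiftDatum]
    shieldings: list[ShieldingTensor]
    truth: SyntheticTruth


# known affine maps of the synthetic world: shielding -> "computed" shift,
# and computed shift -> underlying true shift (the systematic DFT-style
# distortion that shift scaling is meant to undo)
_SHIELD_TO_SHIFT = {"C13": (185.0, -1.0), "H1": (31.0, -0.98)}  # (a, b): δ = a + b σ_iso
_SHIFT_DISTORTION = {"C13": (1.8, 0.97), "H1": (0.05, 0.99)}  # (α, β): δ_true = α + β δ_calc


def make_shieldings(
    ensemble: ConformationalEnsemble,
    seed: int = 0,
    aniso_range: tuple[float, float] = (30.0, 200.0),
    iso_jitter_ppm: float = 2.5,
    orient_jitter_deg: float = 10.0,
) -> list[ShieldingTensor]:
    """Seeded per-(conformer, carbon) shielding tensors, ppm.

    Each carbon gets a base tensor — isotropic part uniform in [10, 170]
    ppm, anisotropy Δσ log-uniform over *aniso_range*, asymmetry uniform,
    orientation uniform over rotations — perturbed per conformer by a small
    reorientation and isotropic jitter, emulating the conformational
    dependence of DFT shieldings.
    """
    rng = np.random.default_rng(seed)
    ref = ensemble.conformers[0]
    out: list[ShieldingTensor] = []
    for label, element in zip(ref.atom_labels, ref.elements):
        if element != "C":
            continue
        iso = rng.uniform(10.0, 170.0)
        dsig = np.exp(rng.uniform(np.log(aniso_range[0]), np.log(aniso_range[1])))
        eta = rng.uniform(0.0, 1.0)
        principal = np.diag([
            -dsig * (1 + eta) / 3.0, -dsig * (1 - eta) / 3.0, 2.0 * dsig / 3.0
        ])
        rot0 = _random_rotation(rng)
        base = rot0 @ principal @ rot0.T
        for conf in ensemble.conformers:
            wobble = _random_rotation(rng)
            angle = rng.normal(0.0, orient_jitter_deg)
            # small reorientation: rotate about a random axis by a small angle
            axis = wobble[:, 0]
            r = _axis_rotation(axis, angle)
            tensor = r @ base @ r.T + np.eye(3) * (iso + rng.normal(0.0, iso_jitter_ppm))
            out.append(ShieldingTensor(conf.conformer_id, label, tensor))
    return out


def _bonded_ch_pairs(conformer: Conformer) -> list[tuple[str, str]]:
    """One-bond C–H pairs, inferred from distances."""
    pairs = []
    for i, (la, ea) in enumerate(zip(conformer.atom_labels, conformer.elements)):
        if ea != "H":
            continue
        best = None
        for j, (lb, eb) in enumerate(zip(conformer.atom_labels, conformer.elements)):
            if eb != "C":
                continue
            d = float(np.linalg.norm(conformer.coords[i] - conformer.coords[j]))
            if best is None or d < best[0]:
                best = (d, lb)
        if best is not None and best[0] < 1.3:
            pairs.append((best[1], la))
    return pairs


def _h_iso_shieldings(
    ensemble: ConformationalEnsemble, seed: int, jitter_ppm: float = 0.15
) -> dict[tuple[str, str], float]:
    rng = np.random.default_rng(seed)
    ref = ensemble.conformers[0]
    out: dict[tuple[str, str], float] = {}
    for label, element in zip(ref.atom_labels, ref.elements):
        if element != "H":
            continue
        base = rng.uniform(24.0, 32.0)
        for conf in ensemble.conformers:
            out[(conf.conformer_id, label)] = base + rng.normal(0.0, jitter_ppm)
    return out


def simulate_dataset(
    ensemble: ConformationalEnsemble,
    truth: SyntheticTruth,
    n_rdc: int | None = None,
    n_rcsa: int | None = None,
    shieldings: list[ShieldingTensor] | None = None,
) -> SimulatedData:
    """Back-calculate noisy RDC/ΔΔRCSA/shift tables from the ground truth.

    RDCs cover every one-bond C–H pair and RCSAs every carbon (optionally
    subsampled to *n_rdc*/*n_rcsa* rows, seeded).  The RCSA table is
    emitted EXTERNAL-referenced; reference schemes are applied at fit time.
    Noise sigmas of zero are recorded as sigma 1.0 in the emitted tables
    (uniform weighting) since a measurement row must carry a positive
    uncertainty.
    """
    pops = truth.true_populations
    missing = [c for c in ensemble.conformer_ids if c not in pops.weights]
    if missing:
        raise ValidationError(f"truth populations missing conformers {missing}")
    rng = np.random.default_rng(truth.seed)
    if shieldings is None:
        shieldings = make_shieldings(ensemble, seed=truth.seed + 1)
    smap = shielding_map(shieldings)
    s_vec = truth.true_tensor.to_vector()

    # --- RDC block
    pairs = _bonded_ch_pairs(ensemble.conformers[0])
    if n_rdc is not None and n_rdc < len(pairs):
        idx = sorted(rng.choice(len(pairs), size=n_rdc, replace=False))
        pairs = [pairs[i] for i in idx]
    clean_rdc = []
    for la, lb in pairs:
        val = 0.0
        for conf in ensemble.conformers:
            pair = DipolarPair.from_conformer(conf, la, lb)
            val += pops[conf.conformer_id] * float(rdc_coefficients(pair) @ s_vec)
        clean_rdc.append(val)
    clean_rdc = np.array(clean_rdc)
    sig_rdc = truth.noise.sigma_rdc_hz
    if truth.noise.relative is not None:
        sig_rdc = truth.noise.relative * float(np.sqrt(np.mean(clean_rdc**2)))
    noisy_rdc = clean_rdc + (rng.normal(0.0, sig_rdc, size=len(pairs))
                             if sig_rdc > 0 else 0.0)
    rdcs = [
        RDCDatum(la, lb, float(v), sig_rdc if sig_rdc > 0 else 1.0)
        for (la, lb), v in zip(pairs, noisy_rdc)
    ]

    # --- RCSA block (all carbons, EXTERNAL reference)
    ref_conf = ensemble.conformers[0]
    carbons = [l for l, e in zip(ref_conf.atom_labels, ref_conf.elements) if e == "C"]
    if n_rcsa is not None and n_rcsa < len(carbons):
        idx = sorted(rng.choice(len(carbons), size=n_rcsa, replace=False))
        carbons = [carbons[i] for i in idx]
    clean_rcsa = []
    for label in carbons:
        val = 0.0
        for conf in ensemble.conformers:
            val += pops[conf.conformer_id] * back_calc_rcsa(
                smap[(conf.conformer_id, label)], truth.true_tensor
            )
        clean_rcsa.append(val)
    clean_rcsa = np.array(clean_rcsa)
    sig_rcsa = truth.noise.sigma_rcsa_ppb
    if truth.noise.relative is not None:
        sig_rcsa = truth.noise.relative * float(np.sqrt(np.mean(clean_rcsa**2)))
    noisy_rcsa = clean_rcsa + (rng.normal(0.0, sig_rcsa, size=len(carbons))
                               if sig_rcsa > 0 else 0.0)
    rcsas = [
        RCSADatum(label, float(v), sig_rcsa if sig_rcsa > 0 else 1.0, EXTERNAL)
        for label, v in zip(carbons, noisy_rcsa)
    ]

    # --- chemical shifts: computed per conformer via the known affine map
    # of isotropic shieldings; experimental = distorted population average
    # plus noise
    h_iso = _h_iso_shieldings(ensemble, seed=truth.seed + 2)
    shifts: list[ShiftDatum] = []
    for label, element in zip(ref_conf.atom_labels, ref_conf.elements):
        if element == "C":
            nucleus, sig_shift = "C13", truth.noise.sigma_c13_ppm
            iso = {c.conformer_id: smap[(c.conformer_id, label)].isotropic
                   for c in ensemble.conformers}
        elif element == "H":
            nucleus, sig_shift = "H1", truth.noise.sigma_h1_ppm
            iso = {c.conformer_id: h_iso[(c.conformer_id, label)]
                   for c in ensemble.conformers}
        else:
            continue
        a, b = _SHIELD_TO_SHIFT[nucleus]
        computed = {cid: a + b * v for cid, v in iso.items()}
        alpha, beta = _SHIFT_DISTORTION[nucleus]
        avg_true = sum(pops[cid] * (alpha + beta * d) for cid, d in computed.items())
        exp = avg_true + (rng.normal(0.0, sig_shift) if sig_shift > 0 else 0.0)
        shifts.append(ShiftDatum(label, nucleus, float(exp), computed))

    return SimulatedData(rdcs=rdcs, rcsas=rcsas, shifts=shifts,
                         shieldings=list(shieldings), truth=truth)


def perturb_computed_shifts(
    shifts: Sequence[ShiftDatum],
    seed: int,
    sigma_c13_ppm: float = 0.5,
    sigma_h1_ppm: float = 0.05,
) -> list[ShiftDatum]:
    """Computed-shift table for a wrong configuration.

    Adds one seeded per-atom offset to every conformer's computed value
    (diastereomers shift by roughly this much at every position), leaving
    the experimental values untouched.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in shifts:
        off = rng.normal(0.0, sigma_c13_ppm if s.nucleus == "C13" else sigma_h1_ppm)
        out.append(replace(s, computed={c: v + off for c, v in s.computed.items()}))
    return out


def _bonds(conformer: Conformer, factor: float = 1.15) -> list[set[int]]:
    """Covalent bonds by distance.  The 1.15 radius factor keeps genuine
    (jittered) bonds while excluding the tight nonbonded contacts that
    rigid rotamer scans can produce."""
    n = conformer.n_atoms
    adj: list[set[int]] = [set() for _ in range(n)]
    radii = [_COVALENT_RADII.get(e, 0.9) for e in conformer.elements]
    d = np.linalg.norm(
        conformer.coords[:, None, :] - conformer.coords[None, :, :], axis=-1
    )
    for i in range(n):
        for j in range(i + 1, n):
            if conformer.elements[i] == "H" and conformer.elements[j] == "H":
                continue  # H-H bonds do not occur in these molecules
            if d[i, j] < factor * (radii[i] + radii[j]):
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _branch(adj: list[set[int]], start: int, exclude: int) -> list[int]:
    seen = {exclude, start}
    stack = [start]
    order = [start]
    while stack:
        for nb in sorted(adj[stack.pop()]):
            if nb not in seen:
                seen.add(nb)
                order.append(nb)
                stack.append(nb)
    return order


def make_decoy_configuration(
    ensemble: ConformationalEnsemble,
    stereocenter_label: str,
    configuration_label: str | None = None,
) -> ConformationalEnsemble:
    """Invert one stereocenter in every conformer (the diastereomer decoy).

    The four substituent branches are identified from distance-inferred
    connectivity; the two smallest branches are exchanged by reflecting
    both through the plane that bisects their bond directions at the
    center.  The reflection is an isometry, so bond lengths are preserved
    exactly and applying the operation twice restores the original
    geometry.  Branches that cannot be told apart (equal size and
    composition) make the inversion ill-defined and raise an error.
    """
    if configuration_label is None:
        configuration_label = ensemble.configuration_label + "-decoy"
    new_conformers = []
    for conf in ensemble.conformers:
        center = conf.index(stereocenter_label)
        adj = _bonds(conf)
        neighbors = sorted(adj[center])
        if len(neighbors) != 4:
            raise AnisofitError(
                f"{stereocenter_label!r} has {len(neighbors)} bonded neighbors "
                "in conformer "
                f"{conf.conformer_id!r}; a stereocenter needs exactly 4"
            )
        branches = [_branch(adj, nb, center) for nb in neighbors]
        signatures = [
            (len(br), tuple(sorted(conf.elements[i] for i in br)))
            for br in branches
        ]
        order = sorted(range(4), key=lambda i: signatures[i])
        if signatures[order[0]] == signatures[order[1]]:
            atoms = [conf.atom_labels[branches[order[0]][0]],
                     conf.atom_labels[branches[order[1]][0]]]
            raise AnisofitError(
                f"stereocenter {stereocenter_label!r}: branches rooted at "
                f"{atoms} are indistinguishable (equal size and composition); "
                "cannot define the inversion"
            )
        b1, b2 = branches[order[0]], branches[order[1]]
        p0 = conf.coords[center]
        u1 = conf.coords[b1[0]] - p0
        u2 = conf.coords[b2[0]] - p0
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        normal = u1 - u2
        normal /= np.linalg.norm(normal)
        coords = conf.coords.copy()
        moved = sorted(set(b1) | set(b2))
        rel = coords[moved] - p0
        coords[moved] = rel - 2.0 * np.outer(rel @ normal, normal) + p0
        # sanity: the inverted geometry must not collide with the rest
        still = [i for i in range(conf.n_atoms) if i not in moved and i != center]
        dists = np.linalg.norm(
            coords[moved][:, None, :] - coords[still][None, :, :], axis=-1
        )
        if dists.min() < 0.9:
            mi, si = np.unravel_index(np.argmin(dists), dists.shape)
            raise AnisofitError(
                f"inverting {stereocenter_label!r} in conformer "
                f"{conf.conformer_id!r} places {conf.atom_labels[moved[mi]]!r} "
                f"{dists.min():.2f} Å from {conf.atom_labels[still[si]]!r}; "
                "geometry too crowded for a clean inversion"
            )
        new_conformers.append(
            Conformer(conf.conformer_id, conf.atom_labels, conf.elements, coords)
        )
    return ConformationalEnsemble(configuration_label, tuple(new_conformers))
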