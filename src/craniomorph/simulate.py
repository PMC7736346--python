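"""Synthetic landmark datasets with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a bilaterally symmetric template configuration, group mean-shape
offsets of controllable Procrustes magnitude, within-group covariance of
controllable generalized variance confined to a low-dimensional symmetric
shape subspace, bilateral asymmetry noise, lognormal centroid size with an
optional allometric coupling of shape to log size, random rigid motion, and
configurable missing-landmark patterns.  Every draw is deterministic given
the seed, and a :class:`SimulationTruth` records the planted quantities so
parameter-recovery tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import Dataset, SpecimenRecord
from .scheme import EXTANT_GROUPS, LandmarkScheme, default_scheme
from .superimpose import procrustes_distance


@dataclass
class GroupSpec:
    """Design of one synthetic group."""
    label: str
    n: int
    mean_offset_magnitude: float = 0.0   # Procrustes distance from template
    gv_scale: float = 1.0                # generalized variance multiplier
    covariance_model: str = "diagonal"   # isotropic | diagonal | factor
    sigma: float = 0.03                  # overall within-group shape scale
    offset_direction_seed: Optional[int] = None  # groups sharing a seed share
                                                 # their offset direction


@dataclass
class SimulationSpec:
    """Full design of a synthetic study."""
    groups: list[GroupSpec]
    scheme: Optional[LandmarkScheme] = None
    n_variation_dims: int = 6            # dimension of the shape subspace
    spectrum_decay: float = 0.6          # eigenvalue decay of the base covariance
    gv_eval_dim: int = 6                 # dimension on which gv_scale is defined:
                                         # every covariance axis is multiplied by
                                         # gv_scale**(1/gv_eval_dim), so any common
                                         # gv_eval_dim-dimensional projection has
                                         # det ratio = gv_scale ratio
    asymmetry_sd: float = 0.0            # per-coordinate bilateral noise (shape units)
    allometric_slope: float = 0.0        # shape shift per unit log size
    size_mean: float = 1150.0            # mm (239-point cranial centroid size)
    size_sd: float = 40.0                # mm
    missing_rate: float = 0.0            # expected missing fraction per specimen
    missing_mechanism: str = "random"    # random | bilateral-biased
    missing_specimens: Optional[int] = None  # cap how many specimens lose points
    outliers: dict = field(default_factory=dict)  # specimen_id -> deviation multiplier
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for g in self.groups:
            if g.n < 1:
                raise ValueError(f"group {g.label}: n must be >= 1")
            if g.gv_scale <= 0:
                raise ValueError(f"group {g.label}: gv_scale must be positive")


@dataclass
class SimulationTruth:
    """Planted quantities of one simulated dataset."""
    template: np.ndarray                        # (k, 3), unit centroid size
    group_means: dict[str, np.ndarray]          # unit-size mean shapes
    group_covariances: dict[str, np.ndarray]    # (q, q) in the shape basis
    basis: np.ndarray                           # (3k, q) orthonormal shape directions
    allometric_direction: np.ndarray            # (3k,)
    procrustes_distances: dict[tuple[str, str], float]
    gv_ratios: dict[tuple[str, str], float]     # over the full shape subspace
    deleted_landmarks: dict[str, list[int]] = field(default_factory=dict)
    log_sizes: dict[str, float] = field(default_factory=dict)


def make_template(kind: str = "parametric",
                  scheme: Optional[LandmarkScheme] = None) -> np.ndarray:
    """Deterministic bilaterally symmetric cranium-proxy configuration.

    Midline points sit exactly on the x = 0 plane; each bilateral pair is
    an exact mirror image across it.  Points lie on an ellipsoidal vault
    with a projecting face scaffold; unit centroid size.
    """
    scheme = scheme or default_scheme()
    k = len(scheme)
    coords = np.zeros((k, 3))
    a, b, c = 0.75, 1.0, 0.80  # ellipsoid semi-axes (x: lateral, y: ant-post, z: vert)

    mid = scheme.midline_indices
    # midsagittal profile from face (front, low) over the vault to the rear
    t = np.linspace(-0.35 * np.pi, 1.1 * np.pi, len(mid))
    face_bulge = 0.25 * np.exp(-((t + 0.2 * np.pi) ** 2) / 0.3)  # projecting face
    coords[mid, 0] = 0.0
    coords[mid, 1] = (b + face_bulge) * np.cos(t)
    coords[mid, 2] = c * np.sin(t) - 0.15

    pairs: dict[int, list[int]] = {}
    for e in scheme.entries:
        if e.pair_id is not None:
            pairs.setdefault(e.pair_id, []).append(e.landmark_id)
    for rank, pid in enumerate(sorted(pairs)):
        left, right = pairs[pid]
        if scheme.entries[left].laterality != "left":
            left, right = right, left
        u = rank / max(len(pairs) - 1, 1)
        # wind around the vault at varying height and lateral spread
        phi = 2.6 * np.pi * u
        lat = a * (0.35 + 0.65 * np.abs(np.sin(2.1 * np.pi * u + 0.4)))
        y = b * 0.92 * np.cos(phi) * (1 - 0.25 * u)
        z = c * (0.85 * np.sin(phi) * (1 - 0.3 * u) - 0.1) + 0.05 * np.cos(5 * phi)
        coords[left] = [lat, y, z]
        coords[right] = [-lat, y, z]

    coords -= coords.mean(axis=0)
    coords[mid, 0] = 0.0  # exact after centering (centroid x is 0 by symmetry anyway)
    cs = np.sqrt((coords ** 2).sum())
    return coords / cs


def _symmetric_tangent_basis(template: np.ndarray, scheme: LandmarkScheme,
                             q: int, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal basis of q symmetric shape directions.

    Directions are orthogonal to the template (tangent space), to uniform
    translations and to the three infinitesimal rotations, so a planted
    offset of Frobenius norm d survives superimposition as a Procrustes
    distance of (almost exactly) d.
    """
    k = len(scheme)
    perm = scheme.relabel_permutation()
    flip = np.array([-1.0, 1.0, 1.0])
    cols: list[np.ndarray] = []
    t = template.reshape(-1)
    base = [t / np.linalg.norm(t)]
    for ax in range(3):  # translations
        v = np.zeros((k, 3))
        v[:, ax] = 1.0
        base.append(v.reshape(-1) / np.linalg.norm(v))
    gens = (np.array([[0., 0., 0.], [0., 0., -1.], [0., 1., 0.]]),
            np.array([[0., 0., 1.], [0., 0., 0.], [-1., 0., 0.]]),
            np.array([[0., -1., 0.], [1., 0., 0.], [0., 0., 0.]]))
    for g in gens:  # infinitesimal rotations of the template
        w = (template @ g.T).reshape(-1)
        for u in base:
            w = w - (w @ u) * u
        nrm = np.linalg.norm(w)
        if nrm > 1e-10:
            base.append(w / nrm)
    while len(cols) < q:
        v = rng.normal(size=(k, 3))
        v = (v + (v * flip)[perm]) / 2.0          # symmetric component
        v[scheme.midline_indices, 0] = 0.0        # keep midline on the plane
        w = v.reshape(-1)
        for u in base + cols:
            w = w - (w @ u) * u
        nrm = np.linalg.norm(w)
        if nrm > 1e-8:
            cols.append(w / nrm)
    return np.column_stack(cols)


def _antisymmetric_noise(shape: tuple[int, int], scheme: LandmarkScheme,
                         sd: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(scale=sd * np.sqrt(2.0), size=shape)
    perm = scheme.relabel_permutation()
    flip = np.array([-1.0, 1.0, 1.0])
    return (eps - (eps * flip)[perm]) / 2.0


def _base_spectrum(q: int, decay: float, total: float) -> np.ndarray:
    raw = decay ** np.arange(q)
    return raw * (total / raw.sum())


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    qmat, r = np.linalg.qr(a)
    qmat *= np.sign(np.diag(r))
    if np.linalg.det(qmat) < 0:
        qmat[:, 0] = -qmat[:, 0]
    return qmat


def simulate(spec: SimulationSpec,
             roster: Optional[Sequence[tuple[str, str, str]]] = None
             ) -> tuple[Dataset, SimulationTruth]:
    """Draw a synthetic dataset and its ground truth.

    ``roster`` optionally assigns (specimen_id, group, sex) triples; by
    default ids are ``<label>_<i>`` and sexes alternate M/F.
    """
    scheme = spec.scheme or default_scheme()
    k = len(scheme)
    rng = np.random.default_rng(spec.seed)
    template = make_template(scheme=scheme)
    q = spec.n_variation_dims
    basis = _symmetric_tangent_basis(template, scheme, q, rng)
    allom_dir = basis @ _unit(rng.normal(size=q))

    truth = SimulationTruth(template=template, group_means={},
                            group_covariances={}, basis=basis,
                            allometric_direction=allom_dir,
                            procrustes_distances={}, gv_ratios={})
    records: list[SpecimenRecord] = []
    roster_iter = iter(roster) if roster is not None else None
    sigma_log = spec.size_sd / spec.size_mean

    for g in spec.groups:
        if g.offset_direction_seed is not None:
            dir_rng = np.random.default_rng(g.offset_direction_seed)
            offset_dir = basis @ _unit(dir_rng.normal(size=q))
        else:
            offset_dir = basis @ _unit(rng.normal(size=q))
        offset = g.mean_offset_magnitude * offset_dir
        mean_flat = template.reshape(-1) + offset
        mean = _to_unit_shape(mean_flat.reshape(k, 3))
        truth.group_means[g.label] = mean

        lam = _group_spectrum(g, q, spec.spectrum_decay, spec.gv_eval_dim)
        truth.group_covariances[g.label] = np.diag(lam)

        for i in range(g.n):
            if roster_iter is not None:
                sid, group_label, sex = next(roster_iter)
            else:
                sid, group_label = f"{g.label}_{i + 1}", g.label
                sex = "M" if i % 2 == 0 else "F"
            z = rng.normal(size=q) * np.sqrt(lam)
            if sid in spec.outliers:
                # planted outlier: deviation of exactly m x the group RMS
                # magnitude, in the drawn random direction
                m = spec.outliers[sid]
                z *= m * np.sqrt(lam.sum()) / np.linalg.norm(z)
            dev = basis @ z
            log_size = np.log(spec.size_mean) + sigma_log * rng.normal()
            shape_flat = (mean_flat + dev
                          + spec.allometric_slope
                          * (log_size - np.log(spec.size_mean)) * allom_dir)
            shape = shape_flat.reshape(k, 3)
            if spec.asymmetry_sd > 0:
                shape = shape + _antisymmetric_noise((k, 3), scheme,
                                                     spec.asymmetry_sd, rng)
            shape = _to_unit_shape(shape)
            size = float(np.exp(log_size))
            coords = size * shape @ _random_rotation(rng) + rng.normal(scale=50.0, size=3)
            records.append(SpecimenRecord(sid, group_label, sex, coords))
            truth.log_sizes[sid] = log_size

    _apply_missingness(records, scheme, spec, truth, rng)

    labels = [g.label for g in spec.groups]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            truth.procrustes_distances[(a, b)] = procrustes_distance(
                truth.group_means[a], truth.group_means[b])
            # planted generalized-variance ratio on a gv_eval_dim projection
            d = spec.gv_eval_dim
            la = np.diag(truth.group_covariances[a])[:d]
            lb = np.diag(truth.group_covariances[b])[:d]
            truth.gv_ratios[(a, b)] = (float(np.prod(la) / np.prod(lb))
                                       if np.all(lb > 0) else float("nan"))
    return Dataset(scheme, records), truth


def _group_spectrum(g: GroupSpec, q: int, decay: float,
                    eval_dim: int) -> np.ndarray:
    """Within-group eigenvalue spectrum: Sigma_g = gv_scale^(1/eval_dim) *
    Sigma_base, so determinant ratios between groups on any common
    eval_dim-dimensional projection equal their gv_scale ratios."""
    if g.covariance_model == "isotropic":
        base = np.full(q, g.sigma ** 2 / q)
    elif g.covariance_model == "diagonal":
        base = _base_spectrum(q, decay, g.sigma ** 2)
    elif g.covariance_model == "factor":
        nf = max(q // 2, 1)
        base = np.concatenate([_base_spectrum(nf, decay, 0.9 * g.sigma ** 2),
                               np.full(q - nf, 0.1 * g.sigma ** 2 / max(q - nf, 1))])
    else:
        raise ValueError(f"unknown covariance model {g.covariance_model!r}")
    return base * g.gv_scale ** (1.0 / eval_dim)


def _apply_missingness(records, scheme, spec, truth, rng) -> None:
    if spec.missing_rate <= 0:
        return
    k = len(scheme)
    perm = scheme.relabel_permutation()
    idx_all = np.arange(k)
    left = np.array([e.landmark_id for e in scheme.entries if e.laterality == "left"])
    n_victims = spec.missing_specimens if spec.missing_specimens is not None else len(records)
    victims = rng.choice(len(records), size=min(n_victims, len(records)), replace=False)
    for vi in victims:
        r = records[vi]
        n_del = int(np.clip(rng.binomial(k, spec.missing_rate), 1,
                            max(1, int(2 * spec.missing_rate * k))))
        if spec.missing_mechanism == "bilateral-biased":
            pool = left if rng.random() < 0.8 else idx_all
        elif spec.missing_mechanism == "random":
            pool = idx_all
        else:
            raise ValueError(f"unknown missing mechanism {spec.missing_mechanism!r}")
        chosen = rng.choice(pool, size=min(n_del, pool.size), replace=False)
        r.coords[chosen] = np.nan
        truth.deleted_landmarks[r.specimen_id] = sorted(int(c) for c in chosen)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _to_unit_shape(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c ** 2).sum())


# --- the published study design, replayed synthetically --------------------

FOSSIL_ROSTER: list[tuple[str, str, str]] = [
    # (specimen_id, group, sex) for the 26 published Upper Palaeolithic crania
    ("Ko14", "EUP", "M"), ("Sun", "EUP", "M"), ("Ml1", "EUP", "F"),
    ("Mui", "EUP", "F"),
    ("CM1", "MUPswf", "M"), ("CM2", "MUPswf", "F?"), ("Cus", "MUPswf", "M"),
    ("AP1", "MUPswf", "F"),
    ("DV3", "MUPmor", "F"), ("DV13", "MUPmor", "M"), ("DV14", "MUPmor", "M"),
    ("DV15", "MUPmor", "M"), ("DV16", "MUPmor", "M"), ("Pr3", "MUPmor", "M"),
    ("Pr4", "MUPmor", "F"),
    ("CB", "LUPswf", "F"), ("Cha", "LUPswf", "M?"), ("Laf", "LUPswf", "F"),
    ("LP", "LUPswf", "F"), ("SGLR", "LUPswf", "F"),
    ("AC2", "LUPita", "M"), ("AC3", "LUPita", "M"), ("AC4", "LUPita", "M"),
    ("ST1", "LUPita", "F?"), ("ST2", "LUPita", "M"), ("Vil", "LUPita", "M"),
]

# relative generalized variances on the retained shape subspace, emulating
# the published within-group variability ordering
_REPLAY_GV = {"EUP": 0.5, "MUPswf": 0.22, "MUPmor": 0.22,
              "LUPswf": 0.70, "LUPita": 0.70,
              "AmNat": 1.0, "EuS": 0.11, "Inuit": 0.034, "OcPap": 0.004}
_REPLAY_N = {"EUP": 4, "MUPswf": 4, "MUPmor": 7, "LUPswf": 5, "LUPita": 6,
             "AmNat": 11, "EuS": 11, "Inuit": 11, "OcPap": 11}
# mean-shape offsets (Procrustes distance from the grand template), on the
# scale of the published between-group distances (~0.02-0.04)
_REPLAY_OFFSET = {"EUP": 0.020, "MUPswf": 0.022, "MUPmor": 0.022,
                  "LUPswf": 0.032, "LUPita": 0.034,
                  "AmNat": 0.030, "EuS": 0.025, "Inuit": 0.030, "OcPap": 0.035}


def replay_study_design(seed: int = 0) -> tuple[Dataset, SimulationTruth]:
    """Synthetic dataset with the published study's exact design.

    Five fossil groups (n = 4, 4, 7, 5, 6 — the published roster with its
    specimen ids and sexes) plus four extant comparison groups of 11
    specimens each (4 females per group); 18 specimens (13 fossil, 5
    extant) carry missing landmarks, each below 20% of the scheme.
    """
    # the two MUP subsamples emulate one homogeneous paledeme: same mean
    # direction, so the merged-MUP covariance is not inflated by a
    # between-subsample separation (the LUP subsamples, two different
    # techno-complexes, keep independent offsets)
    mup_dir_seed = int((seed * 1_000_003 + 17) % 2**31)
    groups = [GroupSpec(label=g, n=_REPLAY_N[g],
                        mean_offset_magnitude=_REPLAY_OFFSET[g],
                        gv_scale=_REPLAY_GV[g], sigma=0.035,
                        offset_direction_seed=(mup_dir_seed if g in
                                               ("MUPswf", "MUPmor") else None))
              for g in _REPLAY_N]
    roster = list(FOSSIL_ROSTER)
    for g in EXTANT_GROUPS:
        for i in range(11):
            roster.append((f"{g}_{i + 1}", g, "F" if i < 4 else "M"))
    spec = SimulationSpec(groups=groups, asymmetry_sd=0.0005,
                          n_variation_dims=30, spectrum_decay=0.85,
                          allometric_slope=0.0, missing_rate=0.0,
                          outliers={"DV3": 2.5}, seed=seed)
    dataset, truth = simulate(spec, roster=roster)

    # inject missingness into 13 fossil + 5 extant specimens, < 20% each
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    scheme = dataset.scheme
    k = len(scheme)
    fossil_ids = [r[0] for r in FOSSIL_ROSTER]
    extant_ids = [r.specimen_id for r in dataset if r.group in EXTANT_GROUPS]
    victims = list(rng.choice(fossil_ids, size=13, replace=False))
    victims += list(rng.choice(extant_ids, size=5, replace=False))
    for sid in victims:
        rec = dataset.get(sid)
        frac = rng.uniform(0.02, 0.19)
        chosen = rng.choice(k, size=int(frac * k), replace=False)
        rec.coords[chosen] = np.nan
        truth.deleted_landmarks[sid] = sorted(int(c) for c in chosen)
    return dataset, truth
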