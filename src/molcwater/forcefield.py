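"""Water-model parameter sets and their coarse-grained re-expression.

A rigid three- or four-site water model (SPC/E, TIP3P-Ew, TIP4P/2005) is
re-expressed as a single spherical bead whose mass is the molecular mass and
whose radius is the Lennard-Jones sigma of the parent model.  The point
charges of the atomistic model are kept verbatim as "off-center" virtual
charges: their positions are fixed in the bead body frame and reconstructed
at run time from the bead position and quaternion, so the coarse model has
exactly the same intermolecular energy surface as the atomistic one.

Body-frame convention: the bead origin sits on the oxygen (the LJ site), the
molecular C2 axis points along +x (towards the hydrogens), and the molecule
lies in the z = 0 plane with the hydrogens symmetric about x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AtomSite",
    "WaterModelSpec",
    "build_model",
    "inertia_tensor",
    "load_model",
    "available_models",
    "ForceFieldError",
]

_CHARGE_TOL = 1e-12

# canonical spellings of the shipped models -> data file stem
_SHIPPED = {
    "SPC-E": "spce",
    "TIP3P-EW": "tip3p_ew",
    "TIP4P-05": "tip4p_05",
}


class ForceFieldError(ValueError):
    """Invalid or inconsistent force-field input."""


@dataclass(frozen=True)
class AtomSite:
    """One interaction site of the atomistic representation.

    Massless virtual sites (e.g. the TIP4P M site) are allowed; at most one
    site carries a Lennard-Jones potential.
    """

    name: str
    mass: float  # g/mol
    charge: float  # e
    position_body: np.ndarray  # (3,) A, molecular body frame
    has_lj: bool = False
    lj_sigma: float = 0.0  # A
    lj_epsilon: float = 0.0  # kcal/mol

    def __post_init__(self):
        object.__setattr__(
            self, "position_body", np.asarray(self.position_body, dtype=float)
        )
        if self.mass < 0:
            raise ForceFieldError(f"site {self.name}: negative mass")


@dataclass(frozen=True)
class WaterModelSpec:
    """Full parameterization of one water model in AA and CG form.

    ``charge_sites`` is a 1-to-1 rigid copy of the charged atomistic sites
    expressed in the bead body frame; ``bead_radius`` equals the LJ sigma of
    the parent model.
    """

    name: str
    atom_sites: tuple[AtomSite, ...]
    bead_mass: float  # g/mol
    bead_radius: float  # A
    charge_sites: tuple[tuple[float, np.ndarray], ...]  # (q [e], S [A])
    inertia_mode: str = "sphere"  # {"sphere", "atomistic"}
    sphere_radius_factor: float = 1.0  # inertia sphere radius = factor * bead_radius
    com_offset_body: np.ndarray = field(default=None)  # (3,) A
    inertia_tensor_body: np.ndarray = field(default=None)  # (3,3) g/mol*A^2

    def __post_init__(self):
        object.__setattr__(self, "atom_sites", tuple(self.atom_sites))
        object.__setattr__(
            self,
            "charge_sites",
            tuple((float(q), np.asarray(s, dtype=float)) for q, s in self.charge_sites),
        )
        if self.com_offset_body is None:
            object.__setattr__(self, "com_offset_body", self._compute_com())
        else:
            object.__setattr__(
                self, "com_offset_body", np.asarray(self.com_offset_body, dtype=float)
            )
        if self.inertia_tensor_body is None:
            object.__setattr__(
                self, "inertia_tensor_body", inertia_tensor(self, self.inertia_mode)
            )
        else:
            object.__setattr__(
                self,
                "inertia_tensor_body",
                np.asarray(self.inertia_tensor_body, dtype=float),
            )

    def _compute_com(self) -> np.ndarray:
        m = np.array([s.mass for s in self.atom_sites])
        r = np.array([s.position_body for s in self.atom_sites])
        if m.sum() <= 0:
            raise ForceFieldError("model has no mass")
        return m @ r / m.sum()

    # -- derived views -----------------------------------------------------

    @property
    def total_charge(self) -> float:
        return float(sum(q for q, _ in self.charge_sites))

    @property
    def lj_site(self) -> AtomSite:
        ljs = [s for s in self.atom_sites if s.has_lj]
        if len(ljs) != 1:
            raise ForceFieldError(f"{self.name}: expected exactly one LJ site")
        return ljs[0]

    @property
    def charges(self) -> np.ndarray:
        return np.array([q for q, _ in self.charge_sites])

    @property
    def charge_offsets(self) -> np.ndarray:
        """(n_charges, 3) body-frame positions S_i of the virtual charges."""
        return np.array([s for _, s in self.charge_sites])

    @property
    def atom_positions_body(self) -> np.ndarray:
        return np.array([s.position_body for s in self.atom_sites])

    @property
    def atom_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.atom_sites)

    def validate(self) -> None:
        """Check every structural invariant; raise ForceFieldError on failure."""
        if abs(self.total_charge) > _CHARGE_TOL:
            raise ForceFieldError(
                f"{self.name}: net charge {self.total_charge:g} e is not zero"
            )
        n_lj = sum(s.has_lj for s in self.atom_sites)
        if n_lj != 1:
            raise ForceFieldError(f"{self.name}: {n_lj} LJ sites (need exactly 1)")
        for q, s in self.charge_sites:
            if np.linalg.norm(s) >= self.bead_radius:
                raise ForceFieldError(
                    f"{self.name}: charge offset |S|={np.linalg.norm(s):.4f} A "
                    f"outside bead radius {self.bead_radius:.4f} A"
                )
        # hydrogens confined to the molecular plane z = 0
        for site in self.atom_sites:
            if site.name.startswith("H") and abs(site.position_body[2]) > 1e-12:
                raise ForceFieldError(f"{self.name}: hydrogen off the z=0 plane")
        it = self.inertia_tensor_body
        if not np.allclose(it, it.T, atol=1e-12):
            raise ForceFieldError(f"{self.name}: inertia tensor not symmetric")
        if np.any(np.linalg.eigvalsh(it) <= 0):
            raise ForceFieldError(f"{self.name}: inertia tensor not positive definite")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "molcwater-model-1",
            "name": self.name,
            "bead_mass": self.bead_mass,
            "bead_radius": self.bead_radius,
            "inertia_mode": self.inertia_mode,
            "sphere_radius_factor": self.sphere_radius_factor,
            "atom_sites": [
                {
                    "name": s.name,
                    "mass": s.mass,
                    "charge": s.charge,
                    "position_body": [float(x) for x in s.position_body],
                    "has_lj": s.has_lj,
                    "lj_sigma": s.lj_sigma,
                    "lj_epsilon": s.lj_epsilon,
                }
                for s in self.atom_sites
            ],
            "charge_sites": [
                {"charge": q, "offset": [float(x) for x in s]}
                for q, s in self.charge_sites
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WaterModelSpec":
        if d.get("schema") != "molcwater-model-1":
            raise ForceFieldError(f"unknown model schema {d.get('schema')!r}")
        sites = tuple(
            AtomSite(
                name=s["name"],
                mass=s["mass"],
                charge=s["charge"],
                position_body=np.array(s["position_body"]),
                has_lj=s["has_lj"],
                lj_sigma=s["lj_sigma"],
                lj_epsilon=s["lj_epsilon"],
            )
            for s in d["atom_sites"]
        )
        spec = cls(
            name=d["name"],
            atom_sites=sites,
            bead_mass=d["bead_mass"],
            bead_radius=d["bead_radius"],
            charge_sites=tuple(
                (c["charge"], np.array(c["offset"])) for c in d["charge_sites"]
            ),
            inertia_mode=d.get("inertia_mode", "sphere"),
            sphere_radius_factor=d.get("sphere_radius_factor", 1.0),
        )
        spec.validate()
        return spec

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "WaterModelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_model(name: str, params: dict) -> WaterModelSpec:
    """Construct a water-model spec from a geometry/charge/LJ parameter table.

    ``params`` keys (units in brackets):

    - ``geometry``: ``oh_length`` [A], ``hoh_angle_deg`` [deg]
    - ``charges``: mapping ``O``/``H`` -> charge [e]
    - ``lj``: ``sigma`` [A], ``epsilon`` [kcal/mol] (on the oxygen)
    - ``masses``: ``O``/``H`` [g/mol]
    - ``msite`` (optional, four-site models): ``distance`` [A] from the
      oxygen along the bisector (+x), ``charge`` [e]

    The bead origin is the oxygen/LJ site, the C2 axis is +x and the
    molecule lies in z = 0.
    """
    try:
        geo = params["geometry"]
        d_oh = float(geo["oh_length"])
        theta = math.radians(float(geo["hoh_angle_deg"]))
        q = params["charges"]
        lj = params["lj"]
        masses = params["masses"]
    except KeyError as exc:
        raise ForceFieldError(f"missing force-field parameter: {exc}") from exc

    hx = d_oh * math.cos(theta / 2.0)
    hy = d_oh * math.sin(theta / 2.0)
    sites = [
        AtomSite(
            name="O",
            mass=float(masses["O"]),
            charge=float(q.get("O", 0.0)),
            position_body=np.zeros(3),
            has_lj=True,
            lj_sigma=float(lj["sigma"]),
            lj_epsilon=float(lj["epsilon"]),
        ),
        AtomSite("H1", float(masses["H"]), float(q["H"]), np.array([hx, hy, 0.0])),
        AtomSite("H2", float(masses["H"]), float(q["H"]), np.array([hx, -hy, 0.0])),
    ]
    msite = params.get("msite")
    if msite:
        sites.append(
            AtomSite(
                "M",
                0.0,
                float(msite["charge"]),
                np.array([float(msite["distance"]), 0.0, 0.0]),
            )
        )

    charge_sites = tuple(
        (s.charge, s.position_body.copy()) for s in sites if s.charge != 0.0
    )
    spec = WaterModelSpec(
        name=name,
        atom_sites=tuple(sites),
        bead_mass=float(sum(s.mass for s in sites)),
        bead_radius=float(lj["sigma"]),
        charge_sites=charge_sites,
        inertia_mode=str(params.get("inertia_mode", "sphere")),
        sphere_radius_factor=float(params.get("sphere_radius_factor", 1.0)),
    )
    spec.validate()
    return spec


def inertia_tensor(spec: WaterModelSpec, mode: str, about: str = "origin") -> np.ndarray:
    """Moment-of-inertia tensor of one bead in the body frame, g/mol*A^2.

    ``mode="sphere"``: uniform solid sphere of the bead mass and radius
    ``sphere_radius_factor * bead_radius`` -> isotropic (2/5) m r^2.
    ``mode="atomistic"``: point-mass inertia of the atom sites, about the
    bead origin by default or about the molecular COM (``about="com"``, the
    reference used by the rigid-body integrator in atomistic mode).
    """
    if mode == "sphere":
        r = spec.sphere_radius_factor * spec.bead_radius
        return 0.4 * spec.bead_mass * r * r * np.eye(3)
    if mode != "atomistic":
        raise ForceFieldError(f"unknown inertia mode {mode!r}")
    origin = spec.com_offset_body if about == "com" else np.zeros(3)
    tensor = np.zeros((3, 3))
    for s in spec.atom_sites:
        r = s.position_body - origin
        tensor += s.mass * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    return tensor


def _data_path(stem: str):
    return resources.files("molcwater.data").joinpath(f"{stem}.yaml")


def available_models() -> list[str]:
    return list(_SHIPPED)


def load_model(name_or_path: str) -> WaterModelSpec:
    """Load a shipped model by name (SPC-E, Tip3P-Ew, Tip4P-05) or a YAML path."""
    key = str(name_or_path).upper().replace("/", "-").replace("_", "-")
    if key in _SHIPPED:
        raw = yaml.safe_load(_data_path(_SHIPPED[key]).read_text())
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise ForceFieldError(
                f"unknown model {name_or_path!r}; shipped: {available_models()}"
            )
        raw = yaml.safe_load(p.read_text())
    if raw.get("schema") == "molcwater-model-1":
        return WaterModelSpec.from_dict(raw)
    name = raw.pop("name")
    raw.pop("schema", None)
    return build_model(name, raw)
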