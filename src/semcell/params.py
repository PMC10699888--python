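"""Cell model parameters and the rheology-preserving interaction constants.

A cell of radius ``R_cell``, stiffness ``kappa0`` and viscosity ``eta0`` is
coarse-grained into ``Np`` particles.  The per-pair interaction constants are
derived so that cell-level rheology is preserved for any particle count:

    d_eq  = 2 R_cell (p_d / Np)^(1/3)          equilibrium pair distance
    kappa = kappa0 Np^(-1/3) (1 - lambda Np^(-1/3))   pair stiffness
    u0    = kappa d_eq^2 / (8 rho^2)           potential well depth
    eta   = eta0 * Np^drag_exponent            per-particle drag

with ``p_d`` the sphere close-packing density and ``lambda`` a tuning
coefficient.  The drag exponent defaults to -1 (total translational drag
independent of Np, pair relaxation time eta/kappa ~ 0.01 s at Np = 1000).

The nucleus is a single rigid particle of radius
``R_nuc = R_cell * nuc_volume_fraction^(1/3)`` (10 % of the cell volume by
default).  Nucleus--cytoplasm pairs use a distance-shifted potential so that
the surface-to-surface equilibrium gap equals the cytoplasm--cytoplasm one:
``shift_nuc = R_nuc - d_eq/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from . import units


class InvalidParameterError(ValueError):
    """A model parameter violates its domain."""


@dataclass
class CellModelParams:
    """Cell-level inputs of the coarse-grained model.

    Units: lengths in um, stiffness in N/m, viscosity in N*s/m, mass numeral
    carried with its unit flag (``mass_unit``; the printed table value is
    ambiguous between ng and pg and only scales the nuclear biasing force,
    whose stiffness S is a free constant).
    """

    R_cell: float = 10.0          # cell radius, um
    Np_ref: int = 1000            # reference particles per cell
    p_d: float = 0.74             # sphere close packing density
    rho: float = 2.0              # scaling factor of the potential
    alpha: float = 2.0            # shifting factor of the potential
    kappa0: float = 5e-3          # cell stiffness, N/m
    eta0: float = 5e-3            # cell viscosity, N*s/m
    lambda_: float = 0.75         # tuning coefficient
    cutoff_factor: float = 2.5    # pair cutoff as multiple of d_eq
    m_p: float = 3.1              # cytoplasmic particle mass numeral (for Np_ref)
    mass_unit: str = "ng"         # "ng" (as printed) or "pg"
    m_nuc_factor: float = 50.0    # nucleus mass as multiple of m_p
    nuc_volume_fraction: float = 0.10
    drag_exponent: float = -1.0   # eta_particle = eta0 * Np**drag_exponent
    nuc_drag_factor: float | None = None  # default: m_nuc_factor (mass-proportional)

    def __post_init__(self) -> None:
        positive = {
            "R_cell": self.R_cell, "Np_ref": self.Np_ref, "p_d": self.p_d,
            "rho": self.rho, "alpha": self.alpha, "kappa0": self.kappa0,
            "eta0": self.eta0, "lambda_": self.lambda_,
            "cutoff_factor": self.cutoff_factor, "m_p": self.m_p,
            "m_nuc_factor": self.m_nuc_factor,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be strictly positive, got {value}")
        if not 0 < self.nuc_volume_fraction < 1:
            raise InvalidParameterError(
                f"nuc_volume_fraction must be in (0, 1), got {self.nuc_volume_fraction}")
        if self.mass_unit not in ("ng", "pg"):
            raise InvalidParameterError(f"mass_unit must be 'ng' or 'pg', got {self.mass_unit!r}")

    @property
    def m_p_kg(self) -> float:
        scale = units.KG_PER_NG if self.mass_unit == "ng" else units.KG_PER_PG
        return self.m_p * scale

    @property
    def m_nuc_kg(self) -> float:
        return self.m_nuc_factor * self.m_p_kg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DerivedPairParams:
    """Interaction constants derived from :class:`CellModelParams` at a given Np."""

    Np: int
    d_eq: float           # um
    kappa: float          # N/m
    u0: float             # J
    eta_particle: float   # N*s/m
    eta_nucleus: float    # N*s/m
    r_cut: float          # um (cytoplasm-cytoplasm cutoff)
    R_nuc: float          # um
    shift_nuc: float      # um, distance shift for nucleus-cytoplasm pairs
    shift_nn: float       # um, distance shift for nucleus-nucleus repulsion
    rho: float
    alpha: float
    m_nuc_kg: float

    @property
    def eta_int(self) -> float:
        """Per-particle drag in internal units, J*s/um^2."""
        return self.eta_particle * units.DRAG_SI_TO_INT

    @property
    def eta_nuc_int(self) -> float:
        return self.eta_nucleus * units.DRAG_SI_TO_INT

    @property
    def kappa_int(self) -> float:
        """Pair stiffness in internal units, J/um^2."""
        return self.kappa * units.STIFFNESS_SI_TO_INT

    def cutoff_for(self, type_pair: str) -> float:
        """Interaction cutoff distance (um) for a pair class 'cc', 'nc' or 'nn'."""
        shift = pair_shift(self, type_pair)
        return self.r_cut + shift


def pair_shift(pp: DerivedPairParams, type_pair: str) -> float:
    if type_pair == "cc":
        return 0.0
    if type_pair in ("nc", "cn"):
        return pp.shift_nuc
    if type_pair == "nn":
        return pp.shift_nn
    raise InvalidParameterError(f"unknown type_pair {type_pair!r}")


def derive_pair_params(Np: int, params: CellModelParams) -> DerivedPairParams:
    """Derive the pair interaction constants for a cell of ``Np`` particles.

    Raises
    ------
    InvalidParameterError
        If ``Np < 2`` or the stiffness relation degenerates
        (``lambda * Np^(-1/3) >= 1`` would give kappa <= 0).
    """
    if Np < 2:
        raise InvalidParameterError(f"Np must be >= 2, got {Np}")
    np13 = Np ** (-1.0 / 3.0)
    if params.lambda_ * np13 >= 1.0:
        raise InvalidParameterError(
            f"lambda*Np^(-1/3) = {params.lambda_ * np13:.3f} >= 1: kappa would be <= 0")

    d_eq = 2.0 * params.R_cell * (params.p_d / Np) ** (1.0 / 3.0)      # um
    kappa = params.kappa0 * np13 * (1.0 - params.lambda_ * np13)       # N/m
    u0 = kappa * (d_eq * units.M_PER_UM) ** 2 / (8.0 * params.rho**2)  # J
    eta = params.eta0 * Np ** params.drag_exponent                     # N*s/m
    nuc_factor = params.nuc_drag_factor if params.nuc_drag_factor is not None \
        else params.m_nuc_factor
    R_nuc = params.R_cell * params.nuc_volume_fraction ** (1.0 / 3.0)  # um

    pp = DerivedPairParams(
        Np=Np,
        d_eq=d_eq,
        kappa=kappa,
        u0=u0,
        eta_particle=eta,
        eta_nucleus=eta * nuc_factor,
        r_cut=params.cutoff_factor * d_eq,
        R_nuc=R_nuc,
        shift_nuc=R_nuc - d_eq / 2.0,
        shift_nn=2.0 * R_nuc - d_eq,
        rho=params.rho,
        alpha=params.alpha,
        m_nuc_kg=params.m_nuc_kg,
    )
    assert pp.d_eq < 2 * params.R_cell
    assert pp.u0 > 0 and pp.r_cut > pp.d_eq
    if params.alpha == 2.0:
        # potential minimum must sit exactly at d_eq
        from .potential import pair_force
        f = pair_force(pp.d_eq, pp, "cc")
        assert abs(f) < 1e-12 * pp.u0 / pp.d_eq, "force at d_eq not zero for alpha=2"
    return pp


_PARAM_KEYS = {
    "R_cell", "Np", "Np_ref", "p_d", "rho", "alpha", "kappa0", "eta0", "lambda",
    "lambda_", "m_p", "mass_unit", "m_nuc_factor", "nuc_volume_fraction",
    "cutoff_factor", "drag_exponent", "nuc_drag_factor",
}


def params_from_dict(raw: dict) -> tuple[CellModelParams, int]:
    """Build (CellModelParams, Np) from a parameter-file mapping.

    Keys follow the model table names; ``lambda`` is accepted as an alias for
    ``lambda_`` and ``Np`` for ``Np_ref``.  Unknown keys raise, so typos never
    fall back to silent defaults.
    """
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
    d = dict(raw)
    if "lambda" in d:
        d["lambda_"] = d.pop("lambda")
    Np = int(d.pop("Np", d.get("Np_ref", 1000)))
    if "Np_ref" not in d:
        d["Np_ref"] = Np
    return CellModelParams(**d), Np
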