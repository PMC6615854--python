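"""Parameter blocks for mechanics and chemistry.

Units: lengths in nm, forces in pN, energies in pN·nm, times in s,
concentrations in μM. ``kBT = 4.1 pN·nm`` (room temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

#: molecules per nm^3 at 1 μM
MOLECULES_PER_UM_NM3 = 6.02214076e-7

#: actin monomer contribution to filament length (nm)
MONOMER_SIZE = 2.7

#: monomers in a full-length cylinder
MONOMERS_PER_CYLINDER = 40


@dataclass
class MechanicalParams:
    """Stiffnesses and geometry of the bead–cylinder mechanical model."""

    l0_cylinder: float = 108.0          # nm, equilibrium cylinder length
    lp_actin: float = 17000.0           # nm, actin persistence length
    kBT: float = 4.1                    # pN·nm
    k_stretch_filament: float = 100.0   # pN/nm
    k_bend: float | None = None         # pN·nm; derived from lp if None
    k_vol: float = 1.0e3                # excluded-volume strength
    k_stretch_linker: float = 8.0       # pN/nm
    k_stretch_motor: float = 2.5        # pN/nm
    rest_length_linker: float = 35.0    # nm
    rest_length_motor: float = 200.0    # nm
    k_boundary: float = 10.0            # pN/nm, harmonic wall
    ev_cutoff: float = 300.0            # nm, pair screening distance
    ev_cap_r: float = 1.0               # nm, cap below this separation

    def __post_init__(self) -> None:
        if self.k_bend is None:
            self.k_bend = self.lp_actin * self.kBT / self.l0_cylinder
        for name in ("l0_cylinder", "lp_actin", "kBT", "k_stretch_filament",
                     "k_bend", "k_vol", "k_stretch_linker", "k_stretch_motor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.l0_cylinder >= self.lp_actin:
            raise ValueError("l0_cylinder must be far below lp_actin")

    def replace(self, **kw) -> "MechanicalParams":
        return replace(self, **kw)


@dataclass
class ChemistryParams:
    """Rate constants and mechanochemical feedback parameters.

    Per-end polymerization constants are μM⁻¹s⁻¹, depolymerization s⁻¹
    (in vitro values); the treadmilling factor ``chi`` multiplies all four.
    """

    k_poly_plus: float = 11.6
    k_depoly_plus: float = 1.4
    k_poly_minus: float = 1.3
    k_depoly_minus: float = 0.8
    chi: float = 1.0
    treadmilling: bool = True

    diffusion_actin: float = 2.0e6      # nm²/s (declared default, not paper)
    diffusion_linker: float = 1.0e6
    diffusion_motor: float = 2.0e5
    voxel_edge: float = 500.0           # nm, Kuramoto-length scale

    k_on_linker: float = 0.7            # μM⁻¹s⁻¹ per eligible pair
    k_off_linker: float = 0.3           # s⁻¹ at zero force
    slip_force: float = 17.0            # pN, slip-bond characteristic force

    k_on_motor: float = 0.2             # μM⁻¹s⁻¹ per eligible pair
    k_off_motor: float = 1.7            # s⁻¹ ensemble base rate at F=0
    catch_force: float = 12.6           # pN per-head characteristic force
    heads_per_side: int = 16
    head_attach_rate: float = 0.2       # s⁻¹ per detached head
    head_detach_rate: float = 1.7       # s⁻¹ per attached head at F=0

    v_motor: float = 200.0              # nm/s unloaded walking speed
    stall_force: float = 50.0           # pN per minifilament
    walk_step: float = MONOMER_SIZE     # nm per walk event

    ratchet_delta: float = MONOMER_SIZE  # nm, Brownian-ratchet step
    ratchet_range: float = 108.0        # nm, boundary interaction range

    linker_band: tuple[float, float] = (30.0, 40.0)
    motor_band: tuple[float, float] = (175.0, 225.0)

    monomers_per_event: int = 1         # event batching (desk-scale knob)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if self.chi <= 0 and self.treadmilling:
            raise ValueError("chi must be > 0 unless treadmilling is disabled")
        if self.heads_per_side < 1:
            raise ValueError("heads_per_side must be >= 1")
        for lo, hi in (self.linker_band, self.motor_band):
            if not 0 <= lo < hi:
                raise ValueError("binding band must satisfy 0 <= lo < hi")

    def replace(self, **kw) -> "ChemistryParams":
        return replace(self, **kw)

    @property
    def heads_per_minifilament(self) -> int:
        return 2 * self.heads_per_side


def apply_treadmilling_factor(params: ChemistryParams, chi: float) -> ChemistryParams:
    """Scale all four end rate constants by ``chi``; nothing else changes."""
    if chi <= 0:
        raise ValueError("chi must be > 0")
    return params.replace(
        k_poly_plus=params.k_poly_plus * chi,
        k_depoly_plus=params.k_depoly_plus * chi,
        k_poly_minus=params.k_poly_minus * chi,
        k_depoly_minus=params.k_depoly_minus * chi,
    )
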