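"""Physical and kinetic parameters for the minimal stress-fiber model.

The model is a pair of antiparallel actin-filament bundles anchored by
harmonic springs to two fixed focal-adhesion (FA) points, decorated with
non-muscle myosin II (NMII) motors and alpha-actinin crosslinkers.  All
lengths are in nm, forces in pN, energies in pN*nm, times in s.  Rates are
per second; bimolecular binding rates are per second per free molecule
(and, for site pairs, per eligible pair).

The headline constants (filament counts, copy numbers, FA spring, box,
chi) follow the standard minimal-fiber bundle configuration.  Constants
this class of models inherits from the wider actin literature (moduli
and kinetic rates) are explicit, documented fields with literature-based
defaults; ``calibrate.py`` derives the polymerization pair
(k_poly, k_depoly) from the pool fixed point so the bundles overlap by
~600 nm at filament-growth steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Tuple

__all__ = ["Parameters", "default_parameters", "desk_scale_parameters"]


@dataclass
class Parameters:
    # -- system composition -------------------------------------------------
    n_filaments_per_bundle: int = 20
    init_cylinders_per_filament: int = 1
    box: Tuple[float, float, float] = (1000.0, 1000.0, 6000.0)
    g_actin_init: int = 23000
    n_motor: int = 48
    n_crosslinker: int = 240
    chi: float = 1.0  # multiplicative scaling of both linker on- and off-rates

    # -- focal adhesions ----------------------------------------------------
    fa_rest_length: float = 100.0     # nm
    fa_spring_k: float = 1.0          # pN/nm
    fa_separation: float = 2750.0     # nm, along the box long (z) axis
    # anchors sit on a hex lattice inside the crosslinker binding window so
    # the bundle is born at the alpha-actinin working distance
    anchor_lattice_spacing: float = 32.0  # nm, lateral hex spacing of anchors

    # -- filaments ----------------------------------------------------------
    cylinder_rest_length: float = 108.0   # nm (full cylinder)
    monomers_per_cylinder: int = 40
    monomer_rise: float = 2.7             # nm per G-actin monomer
    k_filament_stretch: float = 100.0     # pN/nm per cylinder
    k_filament_bend: float = 672.0        # pN*nm, (1 - cos theta) modulus

    # -- crosslinkers (alpha-actinin) ---------------------------------------
    linker_rest_length: float = 30.0      # nm
    linker_spring_k: float = 8.0          # pN/nm
    linker_binding_window: Tuple[float, float] = (30.0, 40.0)  # nm

    # -- motors (NMII, one effective spring per minifilament) ---------------
    motor_rest_length: float = 200.0      # nm
    motor_spring_k: float = 2.5           # pN/nm
    motor_binding_window: Tuple[float, float] = (175.0, 225.0)  # nm
    motor_step: float = 6.0               # nm per walk step

    # -- base chemical rates ------------------------------------------------
    k_on_linker: float = 1.0e-2   # 1/s per (eligible pair, free alpha-actinin)
    k_off_linker: float = 1.0 / 3.0  # 1/s, zero-force; lifetime 3 s at chi=1
    k_on_motor: float = 5.0e-4    # 1/s per (eligible pair, free NMII)
    k_off_motor: float = 0.55     # 1/s, zero-force (effective minifilament)
    v_walk0: float = 24.0         # nm/s unloaded walking speed per endpoint
    # calibrated from the pool fixed point (see calibrate.py) so the
    # bundle overlap plateaus at ~600 nm in the default configuration
    k_poly: float = 1.0 / 3000.0  # 1/s per free G-actin per growing tip
    k_depoly: float = 0.6495756342600559  # 1/s per growing tip

    # -- mechanochemical force laws ------------------------------------------
    x_slip: float = 0.3           # nm, Bell slip distance for alpha-actinin
    F_catch: float = 25.0         # pN, catch-bond characteristic force (NMII)
    F_stall: float = 30.0         # pN, effective ensemble stall force
    kT: float = 4.1               # pN*nm

    # -- mechanics ------------------------------------------------------------
    ev_cutoff: float = 28.0       # nm, excluded-volume cutoff between segments
                                  # (just under the linker rest length so
                                  # crosslinked pairs can settle at 30 nm)
    ev_k: float = 2.0             # pN/nm, excluded-volume overlap stiffness
    boundary_range: float = 50.0  # nm, repulsive layer at box faces
    boundary_k: float = 10.0      # pN/nm
    force_tol: float = 1.0        # pN, minimization residual-force target
    cg_maxiter: int = 2000        # iteration cap per minimization call

    # -- run control ----------------------------------------------------------
    sync_dt: float = 0.025        # s, chemistry/mechanics coupling interval
    sample_dt: float = 1.0        # s, observable sampling interval
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on the first violated parameter invariant."""
        counts = {
            "n_filaments_per_bundle": self.n_filaments_per_bundle,
            "init_cylinders_per_filament": self.init_cylinders_per_filament,
            "g_actin_init": self.g_actin_init,
            "n_motor": self.n_motor,
            "n_crosslinker": self.n_crosslinker,
            "monomers_per_cylinder": self.monomers_per_cylinder,
        }
        for name, v in counts.items():
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        positive = {
            "chi": self.chi,
            "fa_rest_length": self.fa_rest_length,
            "fa_spring_k": self.fa_spring_k,
            "fa_separation": self.fa_separation,
            "cylinder_rest_length": self.cylinder_rest_length,
            "monomer_rise": self.monomer_rise,
            "k_filament_stretch": self.k_filament_stretch,
            "k_filament_bend": self.k_filament_bend,
            "linker_rest_length": self.linker_rest_length,
            "linker_spring_k": self.linker_spring_k,
            "motor_rest_length": self.motor_rest_length,
            "motor_spring_k": self.motor_spring_k,
            "motor_step": self.motor_step,
            "k_on_linker": self.k_on_linker,
            "k_off_linker": self.k_off_linker,
            "k_on_motor": self.k_on_motor,
            "k_off_motor": self.k_off_motor,
            "v_walk0": self.v_walk0,
            "k_poly": self.k_poly,
            "k_depoly": self.k_depoly,
            "x_slip": self.x_slip,
            "F_catch": self.F_catch,
            "F_stall": self.F_stall,
            "kT": self.kT,
            "ev_cutoff": self.ev_cutoff,
            "ev_k": self.ev_k,
            "force_tol": self.force_tol,
            "sync_dt": self.sync_dt,
            "sample_dt": self.sample_dt,
        }
        for name, v in positive.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError(f"box must be three positive lengths, got {self.box!r}")
        lo, hi = self.linker_binding_window
        if not lo < hi:
            raise ValueError("linker_binding_window requires r_min < r_max")
        lo, hi = self.motor_binding_window
        if not lo < hi:
            raise ValueError("motor_binding_window requires r_min < r_max")
        expected = self.monomers_per_cylinder * self.monomer_rise
        if abs(expected - self.cylinder_rest_length) > 1e-9:
            raise ValueError(
                "monomers_per_cylinder * monomer_rise must equal "
                f"cylinder_rest_length ({expected} != {self.cylinder_rest_length})"
            )
        if self.fa_separation + 2 * self.fa_rest_length >= self.box[2]:
            raise ValueError("box too small along z for FA separation + rest lengths")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = list(self.box)
        d["linker_binding_window"] = list(self.linker_binding_window)
        d["motor_binding_window"] = list(self.motor_binding_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
        kw = dict(d)
        for key in ("box", "linker_binding_window", "motor_binding_window"):
            if key in kw:
                kw[key] = tuple(kw[key])
        p = cls(**kw)
        p.validate()
        return p

    def replace(self, **changes) -> "Parameters":
        p = replace(self, **changes)
        p.validate()
        return p


def default_parameters() -> Parameters:
    """Default configuration of the minimal stress fiber (Table-1 scale).

    20 filaments per bundle, 23,000 G-actin monomers, 48 NMII motors,
    240 alpha-actinin crosslinkers, chi = 1, FA springs of 1 pN/nm with
    100 nm rest length, FA separation 2750 nm in a 1 x 1 x 6 um box.
    """
    p = Parameters()
    p.validate()
    return p


def desk_scale_parameters(
    n_filaments_per_bundle: int = 6,
    seed: int = 0,
    target_overlap: float = 600.0,
    t_measure: float = 220.0,
) -> Parameters:
    """A reduced system for fast parameter sweeps and property tests.

    Scales protein copy numbers with the filament count and recalibrates the
    polymerization pair for the same target bundle overlap, so orderings and
    correlations measured on the small system mirror the full configuration.
    """
    from .calibrate import calibrate_polymerization

    base = default_parameters()
    scale = n_filaments_per_bundle / base.n_filaments_per_bundle
    p = base.replace(
        n_filaments_per_bundle=n_filaments_per_bundle,
        g_actin_init=int(round(base.g_actin_init * scale)),
        n_motor=max(2, int(round(base.n_motor * scale))),
        n_crosslinker=max(4, int(round(base.n_crosslinker * scale))),
        sync_dt=0.25,
        seed=seed,
    )
    k_poly, k_depoly = calibrate_polymerization(
        p, target_overlap=target_overlap, t_measure=t_measure, pool_relax_time=30.0
    )
    return p.replace(k_poly=k_poly, k_depoly=k_depoly)
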