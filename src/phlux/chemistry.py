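"""Acid-base equilibrium engine.

Models the assay medium as a collection of polyprotic buffer species plus a
net strong-ion term, solves the charge balance for pH, generates modelled
titration curves (added acid/base equivalents versus pH), and inverts them.
The inversion is the buffering-capacity correction that turns an observed
pH change into cumulative acid (or base) production.

Conventions
-----------
* Concentrations are mol/L, pH is on the conventional scale, activity
  coefficients are taken as 1 and pKa values as temperature-independent
  constants (assays run isothermally at 30 degrees C).
* ``strong_acid_added`` counts fully dissociated acid equivalents; negative
  values denote strong base.  Produced lactate enters the balance as strong
  acid (pKa 3.8 means it is essentially fully dissociated above pH 5.5);
  ammonium production consumes one proton per molecule and enters as strong
  base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DataError, OperatingRangeError, SolverError

WATER_ION_PRODUCT = 1e-14

#: textbook pKa values used throughout
PKA_LACTATE = 3.8
PKA_ACETATE = 4.75
PKA_FORMATE = 3.75
PKA_AMMONIUM = 9.25
PHOSPHATE_PKAS = (2.15, 7.20, 12.35)

#: pH window each titration mode must span to be usable for quantification
DEFAULT_PH_WINDOWS = {"acid": (4.0, 6.5), "base": (5.5, 7.0)}


def deprotonated_fraction(ph, pka):
    """Fraction of a monoprotic acid present in its deprotonated form.

    Henderson-Hasselbalch identity ``1 / (1 + 10**(pka - ph))``; strictly
    increasing in ``ph``, exactly 0.5 at ``ph == pka``.  Accepts scalars or
    arrays.
    """
    ph = np.asarray(ph, dtype=float)
    pka = np.asarray(pka, dtype=float)
    if not (np.all(np.isfinite(ph)) and np.all(np.isfinite(pka))):
        raise ValueError("ph and pka must be finite")
    out = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return float(out) if out.ndim == 0 else out


def proton_equivalent(ph):
    """Free hydrogen-ion concentration ``10**(-ph)`` in mol/L.

    The intermediate quantity on which titration curves are interpolated;
    defined only for 0 < pH < 14.
    """
    arr = np.asarray(ph, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 14.0):
        raise OperatingRangeError("proton_equivalent requires 0 < pH < 14")
    out = 10.0 ** (-arr)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProtolyteSpecies:
    """A (poly)protic buffer species.

    Parameters
    ----------
    name:
        Label used in error messages and serialized tables.
    pka_values:
        Acid dissociation constants in pH units, strictly ascending.
    total_concentration:
        Analytical concentration of all protonation states, mol/L.
    charge_fully_protonated:
        Charge of the fully protonated form (0 for H3PO4, +1 for NH4+).
    """

    name: str
    pka_values: tuple[float, ...]
    total_concentration: float
    charge_fully_protonated: int = 0

    def __post_init__(self):
        pk = tuple(float(p) for p in self.pka_values)
        if len(pk) == 0:
            raise ValueError(f"{self.name}: pka_values must be non-empty")
        if any(b <= a for a, b in zip(pk, pk[1:])):
            raise ValueError(f"{self.name}: pka_values must be strictly ascending")
        if not self.total_concentration >= 0:
            raise ValueError(f"{self.name}: total_concentration must be >= 0")
        object.__setattr__(self, "pka_values", pk)

    def state_fractions(self, ph):
        """Fractions of each protonation state at ``ph``.

        Returns an array with a trailing axis of length ``n_pka + 1``;
        index ``j`` is the state with ``j`` protons removed.  Computed in
        log10 space for numerical stability far from the pKa values.
        """
        ph = np.asarray(ph, dtype=float)
        pk = np.asarray(self.pka_values)
        steps = ph[..., None] - pk  # log10 weight increments per deprotonation
        logw = np.concatenate(
            [np.zeros(ph.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1
        )
        logw -= logw.max(axis=-1, keepdims=True)
        w = 10.0 ** logw
        return w / w.sum(axis=-1, keepdims=True)

    def mean_charge(self, ph):
        """Average charge per molecule at ``ph``."""
        n = len(self.pka_values)
        charges = self.charge_fully_protonated - np.arange(n + 1)
        return (self.state_fractions(ph) * charges).sum(axis=-1)


def phosphate(total_concentration: float = 0.020) -> ProtolyteSpecies:
    """Phosphate buffer (default 20 mM, the assay medium's buffer salt)."""
    return ProtolyteSpecies("phosphate", PHOSPHATE_PKAS, total_concentration, 0)


def lumped_medium_buffer(
    total_concentration: float = 0.030, pka: float = 6.2
) -> ProtolyteSpecies:
    """Lumped monoprotic stand-in for the residual buffering of a defined
    medium plus the cells themselves.

    The exact composition of a defined assay medium (amino acids, organic
    phosphates, cell-surface groups) is not enumerated here; a single
    effective species with configurable concentration and pKa reproduces
    the empirically relevant behaviour: roughly 15-20 mM of lactate is
    needed to move the default medium from pH 6.5 to 5.75.
    """
    return ProtolyteSpecies("medium_buffering", (pka,), total_concentration, 0)


@dataclass(frozen=True)
class BufferSystem:
    """A buffered solution: protolyte species plus net strong ions.

    ``strong_acid_added`` is the net concentration of fully dissociated
    acid equivalents already present (negative for strong base).  The pH of
    the system is the unique root of the charge balance

        [H+] - Kw/[H+] + sum_i C_i * zbar_i(pH) - strong_acid_added = 0

    which is strictly decreasing in pH, so adding strong acid can never
    raise the solved pH.
    """

    species: tuple[ProtolyteSpecies, ...] = ()
    strong_acid_added: float = 0.0
    water_ion_product: float = WATER_ION_PRODUCT

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))

    def charge_imbalance(self, ph, extra_strong_acid=0.0):
        """Charge-balance residual at ``ph`` (array-safe)."""
        ph = np.asarray(ph, dtype=float)
        h = 10.0 ** (-ph)
        q = h - self.water_ion_product / h
        for sp in self.species:
            q = q + sp.total_concentration * sp.mean_charge(ph)
        return q - self.strong_acid_added - extra_strong_acid

    def with_added_acid(self, equivalents: float) -> "BufferSystem":
        """Copy with ``equivalents`` mol/L of strong acid added (negative
        for strong base)."""
        return replace(
            self, strong_acid_added=self.strong_acid_added + float(equivalents)
        )

    def poised_at(self, ph: float) -> "BufferSystem":
        """Copy whose strong-ion term is set so the resting pH equals ``ph``.

        This is how an assay medium 'set to pH 6.5 with HCl/NaOH' is
        represented: the required strong-ion concentration follows in
        closed form from the charge balance at the target pH.
        """
        resid = float(self.charge_imbalance(ph))
        return replace(self, strong_acid_added=self.strong_acid_added + resid)


def default_assay_medium(start_ph: float | None = None) -> BufferSystem:
    """Surrogate for the defined assay medium: 20 mM phosphate plus a
    30 mM lumped monoprotic buffering species (pKa 6.2), optionally poised
    at ``start_ph``."""
    system = BufferSystem(species=(phosphate(), lumped_medium_buffer()))
    if start_ph is not None:
        system = system.poised_at(start_ph)
    return system


def solve_ph(system: BufferSystem, tol: float = 1e-10) -> float:
    """pH of ``system`` by bracketed root finding of the charge balance.

    The residual is strictly decreasing in pH, so the root in (0, 14) is
    unique whenever the bracket changes sign.
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = float(system.charge_imbalance(lo))
    f_hi = float(system.charge_imbalance(hi))
    if not (f_lo > 0.0 > f_hi):
        raise SolverError(
            "charge balance has no root in (0, 14); the buffer system is "
            "malformed (check concentrations and strong-ion terms)"
        )
    return float(
        brentq(lambda p: float(system.charge_imbalance(p)), lo, hi, xtol=tol)
    )


def solve_ph_many(system: BufferSystem, extra_strong_acid, iterations: int = 60):
    """Vectorized pH solve for an array of strong-acid additions.

    Plain bisection on the monotone charge balance; 60 halvings of a
    14-unit bracket reach ~8e-17 pH, far below any tolerance used here.
    """
    extra = np.asarray(extra_strong_acid, dtype=float)
    lo = np.full(extra.shape, 1e-9)
    hi = np.full(extra.shape, 14.0 - 1e-9)
    if np.any(system.charge_imbalance(lo, extra) <= 0.0) or np.any(
        system.charge_imbalance(hi, extra) >= 0.0
    ):
        raise SolverError("charge balance has no root in (0, 14) for some inputs")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        above = system.charge_imbalance(mid, extra) > 0.0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TitrationCurve:
    """Monotone mapping between added acid/base equivalents and pH.

    ``mode='acid'`` curves have strictly decreasing pH as equivalents of
    strong acid accumulate; ``mode='base'`` curves strictly increasing pH.
    The first point is always at zero added equivalents (the resting pH).
    """

    added_equivalents: np.ndarray
    ph: np.ndarray
    mode: str
    source: str = "modelled"

    def __post_init__(self):
        eq = np.asarray(self.added_equivalents, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        if self.mode not in ("acid", "base"):
            raise DataError(f"unknown titration mode {self.mode!r}")
        if eq.ndim != 1 or eq.shape != ph.shape or eq.size < 1:
            raise DataError("titration curve needs matching 1-D point arrays")
        if abs(eq[0]) > 1e-12:
            raise DataError("titration curve must start at 0 added equivalents")
        if np.any(np.diff(eq) <= 0):
            raise DataError("added equivalents must be strictly increasing")
        dph = np.diff(ph)
        if self.mode == "acid" and np.any(dph >= 0):
            raise DataError("acid-mode titration must have strictly decreasing pH")
        if self.mode == "base" and np.any(dph <= 0):
            raise DataError("base-mode titration must have strictly increasing pH")
        object.__setattr__(self, "added_equivalents", eq)
        object.__setattr__(self, "ph", ph)

    @property
    def ph_range(self) -> tuple[float, float]:
        return (float(self.ph.min()), float(self.ph.max()))

    @property
    def start_ph(self) -> float:
        return float(self.ph[0])

    def _transform_nodes(self):
        # interpolation runs in log10 proton-equivalent space, i.e. -pH
        u = -self.ph
        eq = self.added_equivalents
        if u[0] > u[-1]:  # base mode: reverse so u ascends
            u, eq = u[::-1], eq[::-1]
        return u, eq

    def production_from_ph(self, ph, method: str = "interp", ph_tol: float = 0.05):
        """Added equivalents corresponding to an observed ``ph``.

        Monotone piecewise-linear interpolation of the inverted curve in
        log10 proton-equivalent space (``method='interp'``, default), or a
        single log-linear least-squares fit over the whole curve
        (``method='loglinear'``) for comparison with a one-parameter
        'logarithmic equation' treatment.

        The two ends of the window are treated differently.  Detector
        noise drives readings slightly *past the resting pH* (above it in
        acid mode, below it in base mode); those cannot correspond to any
        production, so they clamp to zero production without error (a
        warning fires beyond ``rest_tol``, which suggests the wrong curve
        is in use).  At the far (signal) end, values up to ``ph_tol``
        beyond the curve are clamped with a warning; larger excursions
        raise :class:`OperatingRangeError`.
        """
        arr = np.atleast_1d(np.asarray(ph, dtype=float))
        lo, hi = self.ph_range
        rest_tol = 0.25
        if self.mode == "acid":
            beyond_far = arr < lo - ph_tol
            beyond_rest = arr > hi + rest_tol
        else:
            beyond_far = arr > hi + ph_tol
            beyond_rest = arr < lo - rest_tol
        if np.any(beyond_far):
            raise OperatingRangeError(
                f"pH outside the operational window [{lo:.3f}, {hi:.3f}] "
                f"of this {self.mode}-mode titration curve"
            )
        if np.any(beyond_rest):
            warnings.warn(
                f"readings more than {rest_tol} pH past the resting pH "
                f"({self.start_ph:.2f}); is this the right titration curve?",
                stacklevel=2,
            )
        clamped = np.clip(arr, lo, hi)
        far_clip = (arr < lo) if self.mode == "acid" else (arr > hi)
        if np.any(far_clip & ~beyond_far & (clamped != arr)):
            warnings.warn(
                f"pH clamped to titration window [{lo:.3f}, {hi:.3f}]",
                stacklevel=2,
            )
        u_nodes, eq_nodes = self._transform_nodes()
        if method == "interp":
            out = np.interp(-clamped, u_nodes, eq_nodes)
        elif method == "loglinear":
            b, a = np.polyfit(u_nodes, eq_nodes, 1)
            out = a + b * (-clamped)
        else:
            raise ValueError(f"unknown inversion method {method!r}")
        return float(out[0]) if np.ndim(ph) == 0 else out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"added_equivalents_mol_per_L": self.added_equivalents, "ph": self.ph}
        )


def model_titration(
    system: BufferSystem,
    mode: str,
    grid: Sequence[float],
    required_ph_window: tuple[float, float] | None | str = "auto",
) -> TitrationCurve:
    """Modelled titration curve: pH solved at each added-equivalents point.

    ``grid`` must start at 0 and be strictly increasing.  In acid mode the
    grid counts strong-acid equivalents; in base mode strong-base
    equivalents.  By default the resulting curve must span the assay
    window for its mode (acid 6.5 -> 4.0; base 5.5 -> 7.0); pass
    ``required_ph_window=None`` to skip the check, or an explicit
    ``(ph_min, ph_max)`` pair.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if abs(grid[0]) > 1e-12:
        raise ValueError("grid must start at 0 added equivalents")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if mode not in ("acid", "base"):
        raise ValueError(f"unknown titration mode {mode!r}")
    sign = 1.0 if mode == "acid" else -1.0
    ph = solve_ph_many(system, sign * grid)
    dph = np.diff(ph)
    if (mode == "acid" and np.any(dph >= 0)) or (
        mode == "base" and np.any(dph <= 0)
    ):
        raise SolverError("modelled titration curve is not strictly monotone")
    if required_ph_window == "auto":
        required_ph_window = DEFAULT_PH_WINDOWS[mode]
    if required_ph_window is not None:
        lo, hi = required_ph_window
        if ph.min() > lo + 1e-6 or ph.max() < hi - 1e-6:
            raise OperatingRangeError(
                f"modelled {mode}-mode curve spans pH "
                f"[{ph.min():.3f}, {ph.max():.3f}] but must cover "
                f"[{lo}, {hi}]; extend the added-equivalents grid or adjust "
                "the medium"
            )
    return TitrationCurve(grid, ph, mode=mode, source="modelled")


def production_from_ph(curve: TitrationCurve, ph, **kwargs):
    """Functional alias for :meth:`TitrationCurve.production_from_ph`."""
    return curve.production_from_ph(ph, **kwargs)
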