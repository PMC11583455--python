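"""Grid Convergence Index (GCI) mesh-independence analysis.

Richardson-extrapolation-based verification for a three-mesh refinement
sequence with a scalar quantity of interest (here typically the maximum
wall shear stress).  Given QoI values ``phi3, phi2, phi1`` on successively
finer meshes and a refinement ratio ``r``:

* observed order of convergence ``p = log((phi3 - phi2) / (phi2 - phi1)) /
  log(r)`` (undefined when the sequence oscillates);
* ``GCI = 1.25 * |delta_phi / phi_ref| / (r**p - 1)``, reported as a
  percentage, for the coarse/medium (23) and medium/fine (12) pairs;
* asymptotic score ``GCI23 / (r**p * GCI12)``, close to 1 inside the
  asymptotic convergence range.

Conventions
-----------
* The refinement ratio from cell counts is the mean of the successive
  count ratios ``(N_medium/N_coarse, N_fine/N_medium)``.  (The cube-root
  convention ``(N_fine/N_coarse)**(1/3)`` is *not* used: for the published
  carotid studies this package mirrors, only the mean-ratio convention
  reproduces the reported ratios.)
* ``phi_ref`` defaults to the *finer* member of each pair
  (``denominator="finer"``); ``denominator="printed"`` divides by the
  coarser member instead, matching the textbook formula that normalizes
  GCI12 by phi2 and GCI23 by phi3.  Published tables are not always
  consistent about this, so both are exposed.
* Percentages are stored as percentages: 1.31 means 1.31 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GCIStudy",
    "refinement_ratio",
    "convergence_order",
    "gci_pair",
    "asymptotic_score",
    "gci_study",
]

#: a fine-mesh GCI below this is considered adequate for pathological
#: carotid models (stricter than the common 5 % guideline)
ADEQUATE_GCI_PERCENT = 3.0


def refinement_ratio(counts) -> float:
    """Mean of successive cell-count ratios of a coarse/medium/fine triple."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (3,):
        raise ValueError("need exactly three cell counts")
    if np.any(np.diff(c) <= 0):
        raise ValueError("cell counts must be strictly increasing")
    return float(np.mean([c[1] / c[0], c[2] / c[1]]))


def convergence_order(
    phi_coarse: float, phi_medium: float, phi_fine: float, r: float
) -> float:
    """Observed order of convergence of a monotone QoI triple."""
    if r <= 1:
        raise ValueError("refinement ratio must exceed 1")
    d32 = phi_coarse - phi_medium
    d21 = phi_medium - phi_fine
    if d21 == 0:
        raise ZeroDivisionError("phi_medium equals phi_fine")
    ratio = d32 / d21
    if ratio <= 0:
        from .errors import OscillatoryConvergenceError

        raise OscillatoryConvergenceError(
            "QoI sequence is non-monotone; observed order is undefined"
        )
    return float(np.log(ratio) / np.log(r))


def gci_pair(
    phi_coarser: float,
    phi_finer: float,
    r: float,
    p: float,
    which: int = 12,
    denominator: str = "finer",
) -> float:
    """Grid Convergence Index of one mesh pair, in percent.

    ``which`` is 12 (medium/fine) or 23 (coarse/medium) and is recorded for
    reporting only; the arithmetic depends only on the pair's values.
    ``denominator`` selects the normalizing phi: the pair's finer member
    (default) or the coarser one ("printed", the literal textbook form).
    """
    if p <= 0:
        raise ValueError("convergence order must be positive")
    if r**p <= 1:
        raise ValueError("r**p must exceed 1")
    if which not in (12, 23):
        raise ValueError("which must be 12 or 23")
    ref = phi_finer if denominator == "finer" else phi_coarser
    if denominator not in ("finer", "printed", "coarser"):
        raise ValueError("denominator must be 'finer' or 'printed'")
    if ref == 0:
        raise ZeroDivisionError("normalizing phi is zero")
    return float(100.0 * 1.25 * abs((phi_coarser - phi_finer) / ref) / (r**p - 1.0))


def asymptotic_score(gci23: float, gci12: float, r: float, p: float) -> float:
    """``GCI23 / (r**p * GCI12)``; close to 1 in the asymptotic range."""
    if gci12 <= 0:
        raise ZeroDivisionError("GCI12 must be positive")
    return float(gci23 / (r**p * gci12))


@dataclass
class GCIStudy:
    """Complete three-mesh convergence record."""

    cell_counts: np.ndarray  # (3,) coarse, medium, fine
    phi: np.ndarray  # (3,) QoI coarse -> fine (phi3, phi2, phi1)
    qoi_label: str = "max WSS (Pa)"
    r: float = 0.0
    p: float = 0.0
    gci23_percent: float = 0.0
    gci12_percent: float = 0.0
    asymptotic: float = 0.0
    adequate: bool = False
    oscillatory: bool = False
    notes: list = field(default_factory=list)

    def report(self) -> str:
        c = self.cell_counts
        lines = [
            f"GCI mesh-independence study ({self.qoi_label})",
            f"  cells (coarse/medium/fine): {c[0]:.3g} / {c[1]:.3g} / {c[2]:.3g}",
            f"  phi3/phi2/phi1:             {self.phi[0]:.4g} / "
            f"{self.phi[1]:.4g} / {self.phi[2]:.4g}",
            f"  refinement ratio r:         {self.r:.2f}",
        ]
        if self.oscillatory:
            lines.append("  convergence:               OSCILLATORY (p undefined)")
        else:
            lines += [
                f"  convergence order p:        {self.p:.2f}",
                f"  GCI23 / GCI12:              {self.gci23_percent:.2f}% / "
                f"{self.gci12_percent:.2f}%",
                f"  asymptotic score:           {self.asymptotic:.2f}",
                f"  fine-mesh GCI adequate:     "
                f"{'yes' if self.adequate else 'no'} "
                f"(threshold {ADEQUATE_GCI_PERCENT:.0f}%)",
            ]
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cell_counts": list(map(float, self.cell_counts)),
            "phi": list(map(float, self.phi)),
            "qoi_label": self.qoi_label,
            "refinement_ratio": self.r,
            "convergence_order": None if self.oscillatory else self.p,
            "gci23_percent": None if self.oscillatory else self.gci23_percent,
            "gci12_percent": None if self.oscillatory else self.gci12_percent,
            "asymptotic_score": None if self.oscillatory else self.asymptotic,
            "adequate": self.adequate,
            "oscillatory": self.oscillatory,
        }


def gci_study(
    counts,
    phis,
    qoi_label: str = "max WSS (Pa)",
    denominator: str = "finer",
) -> GCIStudy:
    """Run the full three-mesh analysis and flag adequacy.

    An oscillatory QoI triple is reported explicitly (``oscillatory=True``,
    order and GCIs unset) instead of raising.
    """
    from .errors import OscillatoryConvergenceError

    c = np.asarray(counts, dtype=float)
    f = np.asarray(phis, dtype=float)
    if c.shape != (3,) or f.shape != (3,):
        raise ValueError("need three cell counts and three QoI values")
    r = refinement_ratio(c)
    study = GCIStudy(cell_counts=c, phi=f, qoi_label=qoi_label, r=r)
    try:
        p = convergence_order(f[0], f[1], f[2], r)
    except OscillatoryConvergenceError:
        study.oscillatory = True
        study.notes.append("non-monotone QoI sequence: oscillatory convergence")
        return study
    study.p = p
    study.gci23_percent = gci_pair(f[0], f[1], r, p, which=23, denominator=denominator)
    study.gci12_percent = gci_pair(f[1], f[2], r, p, which=12, denominator=denominator)
    study.asymptotic = asymptotic_score(study.gci23_percent, study.gci12_percent, r, p)
    study.adequate = study.gci12_percent < ADEQUATE_GCI_PERCENT
    return study
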