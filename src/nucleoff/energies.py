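"""CRISPRspec-derived binding-energy features.

The biophysical binding model decomposes gRNA-Cas9 binding at an
(off-)target into four empirical free-energy contributions:

* ``delta_pam`` — PAM-dependent correcting factor (dimensionless),
* ``dG_H`` — RNA:DNA hybridization free energy of gRNA and target strand,
* ``dG_U`` — RNA:RNA folding free energy of the 20 nt gRNA spacer,
* ``dG_O`` — DNA:DNA duplex free energy of target/non-target strands.

The total binding free energy is

    dG_B = delta_pam * (dG_H - dG_U - dG_O)

and the three model features derived from the raw terms are

    E_RNA-DNA       = delta_pam * dG_H
    E_RNA-DNA^corr  = delta_pam * (dG_H - dG_O)
    E_gRNAfold      = dG_U

Units are carried opaquely (consistent within a dataset).  The
nearest-neighbor thermodynamics and RNA folding that produce the raw
terms are upstream of this package; the terms are inputs here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class EnergyError(ValueError):
    """Non-finite energy input."""


@dataclass
class EnergyTerms:
    delta_pam: float = math.nan
    dG_H: float = math.nan
    dG_U: float = math.nan
    dG_O: float = math.nan
    e_rna_dna: float = math.nan
    e_rna_dna_corr: float = math.nan
    e_grnafold: float = math.nan
    dG_B: float = math.nan

    def has_raw_terms(self) -> bool:
        return all(
            math.isfinite(v) for v in (self.delta_pam, self.dG_H, self.dG_U, self.dG_O)
        )

    def with_derived(self) -> "EnergyTerms":
        """Fill the derived features from the four raw terms.

        Datasets that store only the three derived features (no raw
        terms) bypass this and are used as-is.
        """
        _check_finite(self.delta_pam, self.dG_H, self.dG_U, self.dG_O)
        e_rna_dna, e_rna_dna_corr, e_grnafold = derive_energy_features(self)
        return EnergyTerms(
            delta_pam=self.delta_pam,
            dG_H=self.dG_H,
            dG_U=self.dG_U,
            dG_O=self.dG_O,
            e_rna_dna=e_rna_dna,
            e_rna_dna_corr=e_rna_dna_corr,
            e_grnafold=e_grnafold,
            dG_B=binding_free_energy(self),
        )


def _check_finite(*values: float) -> None:
    if not all(math.isfinite(v) for v in values):
        raise EnergyError("energy terms must be finite")


def binding_free_energy(t: EnergyTerms) -> float:
    """Total binding free energy dG_B = delta_pam * (dG_H - dG_U - dG_O)."""
    _check_finite(t.delta_pam, t.dG_H, t.dG_U, t.dG_O)
    return t.delta_pam * (t.dG_H - t.dG_U - t.dG_O)


def derive_energy_features(t: EnergyTerms) -> tuple[float, float, float]:
    """The three model features (E_RNA-DNA, E_RNA-DNA^corr, E_gRNAfold)."""
    _check_finite(t.delta_pam, t.dG_H, t.dG_U, t.dG_O)
    e_rna_dna = t.delta_pam * t.dG_H
    e_rna_dna_corr = t.delta_pam * (t.dG_H - t.dG_O)
    e_grnafold = t.dG_U
    return e_rna_dna, e_rna_dna_corr, e_grnafold
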