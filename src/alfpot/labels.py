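"""Recovery-error correction of partitioned atomic energies.

Topological energy partitions reconstruct the molecular energy only up
to a small numerical integration defect, the *recovery error*

    ΔE = E_ref − Σ_A E_A^raw.

The correction redistributes ΔE over atoms proportionally to each
atom's share of the raw molecular energy plus its deviation from the
mean absolute integration error:

    E_A^corr = E_A^raw + ΔE·[ E_A^raw / Σ_B E_B^raw
                              + (|L_A| − mean_B |L_B|) ],

which restores Σ_A E_A^corr = E_ref exactly (the fractional shares sum
to 1 and the deviations sum to 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LabeledConfiguration


@dataclass
class CorrectedLabels:
    corrected_atomic_energies: np.ndarray  # Ha, per atom
    recovery_error: float  # Ha
    n_atoms: int


def correct_energies(cfg: LabeledConfiguration) -> CorrectedLabels:
    """Apply the recovery-error correction to one labeled configuration."""
    raw = cfg.raw_atomic_energies
    labs = cfg.abs_integration_errors
    e_mol_raw = raw.sum()
    if e_mol_raw == 0.0:
        raise ValueError(
            "raw molecular energy is exactly zero; the fractional "
            "redistribution term is undefined"
        )
    delta_e = cfg.ref_molecular_energy - e_mol_raw
    corrected = raw + delta_e * (raw / e_mol_raw + (labs - labs.mean()))
    return CorrectedLabels(corrected, float(delta_e), cfg.geometry.n_atoms)
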