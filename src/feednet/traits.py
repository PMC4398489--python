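"""Trait catalogue for the bovine feed-efficiency analysis.

The analysis works on 14 traits measured on Charolais x Holstein F2 bulls at
the onset of puberty (months 6-9 of age): residual feed intake (RFI, the key
trait), feed conversion ratio (FCR), daily energy intake (dEI), and eleven
plasma metabolites selected for low mutual correlation (two amino acids, six
acylcarnitines, two phosphatidylcholines, one sphingomyelin).  Average daily
gain (ADG) is measured and analysed but is not part of the AWM trait set.

This module holds the descriptive statistics of those traits (means, SDs and
ranges on the published scales), the phenotypic correlation matrix among them,
and the bookkeeping of the targeted metabolomics panel they were drawn from.
Everything downstream (the synthetic-data generator in particular) pulls its
default magnitudes from here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Classes of the targeted plasma metabolomics panel and the number of
#: quantified metabolites per class.
METABOLITE_PANEL_CLASSES: dict[str, int] = {
    "acylcarnitines": 48,
    "amino_acids": 18,
    "lysophosphatidylcholines": 9,
    "phosphatidylcholines": 70,
    "sphingomyelins": 16,
    "biogenic_amines": 8,
    "sugars": 52,
}


def panel_size() -> int:
    """Total number of metabolites quantified by the targeted panel."""
    return sum(METABOLITE_PANEL_CLASSES.values())


#: The eleven metabolites retained as supportive traits (plasma, uM).
METABOLITE_TRAITS: list[str] = [
    "Arg", "Lys", "C0", "C2", "C5", "C8:1", "C14", "C18",
    "PC_aa_C32:0", "PC_ae_C36:1", "SM_C20:2",
]

#: Key trait of the co-association analysis.
KEY_TRAIT = "RFI"

#: Supportive traits, in AWM column order.
SUPPORTIVE_TRAITS: list[str] = ["FCR", "dEI"] + METABOLITE_TRAITS

#: All 14 AWM analysis traits (key first).
ANALYSIS_TRAITS: list[str] = [KEY_TRAIT] + SUPPORTIVE_TRAITS

# Descriptive statistics per trait: (unit, n, mean, minimum, maximum, sd).
# RFI is a regression residual and is zero-mean by construction; the small
# nonzero published average reflects rounding/post-fit exclusions.
TRAIT_STATS: pd.DataFrame = pd.DataFrame.from_records(
    [
        ("RFI", "MJ ME", 175, 0.02, -18.1, 15.4, 5.71),
        ("FCR", "MJ ME/kg", 175, 50.9, 40.3, 68.3, 5.38),
        ("dEI", "MJ ME/day", 237, 77.2, 47.5, 117.0, 9.76),
        ("ADG", "kg/day", 173, 1.49, 0.94, 1.92, 0.18),
        ("Arg", "uM", 148, 93.3, 33.7, 200.0, 21.7),
        ("Lys", "uM", 148, 93.3, 33.7, 200.0, 21.7),
        ("C0", "uM", 149, 6.12, 3.49, 9.99, 0.85),
        ("C2", "uM", 147, 0.96, 0.39, 2.73, 0.36),
        ("C5", "uM", 147, 0.064, 0.026, 0.130, 0.018),
        ("C8:1", "uM", 147, 0.006, 0.001, 0.139, 0.011),
        ("C14", "uM", 147, 0.011, 0.003, 0.027, 0.004),
        ("C18", "uM", 147, 0.021, 0.007, 0.069, 0.011),
        ("PC_aa_C32:0", "uM", 146, 4.72, 1.28, 9.30, 1.65),
        ("PC_ae_C36:1", "uM", 146, 13.4, 4.5, 31.6, 5.1),
        ("SM_C20:2", "uM", 146, 3.44, 0.70, 7.71, 1.52),
    ],
    columns=["trait", "unit", "n", "mean", "min", "max", "sd"],
).set_index("trait")
# Lysine descriptives were not printed separately; it shares the arginine
# scale (both plasma amino acids in the same panel).

# Phenotypic correlations among the 14 analysis traits (upper triangle of the
# published matrix, symmetrised here).  Order follows ANALYSIS_TRAITS.
_PHENO_CORR_UPPER = {
    ("RFI", "FCR"): 0.67, ("RFI", "dEI"): 0.60, ("RFI", "Arg"): -0.05,
    ("RFI", "Lys"): 0.17, ("RFI", "C0"): -0.03, ("RFI", "C2"): -0.11,
    ("RFI", "C5"): -0.06, ("RFI", "C8:1"): 0.04, ("RFI", "C14"): -0.10,
    ("RFI", "C18"): -0.11, ("RFI", "PC_aa_C32:0"): 0.13,
    ("RFI", "PC_ae_C36:1"): 0.18, ("RFI", "SM_C20:2"): 0.23,
    ("FCR", "dEI"): 0.36, ("FCR", "Arg"): -0.27, ("FCR", "Lys"): -0.05,
    ("FCR", "C0"): -0.09, ("FCR", "C2"): -0.04, ("FCR", "C5"): -0.14,
    ("FCR", "C8:1"): 0.00, ("FCR", "C14"): 0.12, ("FCR", "C18"): -0.05,
    ("FCR", "PC_aa_C32:0"): 0.01, ("FCR", "PC_ae_C36:1"): 0.01,
    ("FCR", "SM_C20:2"): 0.10,
    ("dEI", "Arg"): 0.08, ("dEI", "Lys"): 0.32, ("dEI", "C0"): -0.23,
    ("dEI", "C2"): -0.22, ("dEI", "C5"): -0.03, ("dEI", "C8:1"): 0.11,
    ("dEI", "C14"): -0.16, ("dEI", "C18"): -0.08,
    ("dEI", "PC_aa_C32:0"): 0.08, ("dEI", "PC_ae_C36:1"): 0.13,
    ("dEI", "SM_C20:2"): 0.20,
    ("Arg", "Lys"): 0.35, ("Arg", "C0"): 0.43, ("Arg", "C2"): 0.26,
    ("Arg", "C5"): 0.48, ("Arg", "C8:1"): 0.08, ("Arg", "C14"): 0.02,
    ("Arg", "C18"): 0.04, ("Arg", "PC_aa_C32:0"): 0.10,
    ("Arg", "PC_ae_C36:1"): 0.14, ("Arg", "SM_C20:2"): 0.03,
    ("Lys", "C0"): 0.17, ("Lys", "C2"): -0.14, ("Lys", "C5"): 0.29,
    ("Lys", "C8:1"): -0.11, ("Lys", "C14"): -0.10, ("Lys", "C18"): -0.02,
    ("Lys", "PC_aa_C32:0"): -0.03, ("Lys", "PC_ae_C36:1"): 0.05,
    ("Lys", "SM_C20:2"): 0.08,
    ("C0", "C2"): 0.59, ("C0", "C5"): 0.40, ("C0", "C8:1"): -0.07,
    ("C0", "C14"): 0.28, ("C0", "C18"): 0.26, ("C0", "PC_aa_C32:0"): 0.06,
    ("C0", "PC_ae_C36:1"): -0.01, ("C0", "SM_C20:2"): -0.02,
    ("C2", "C5"): 0.10, ("C2", "C8:1"): 0.00, ("C2", "C14"): 0.33,
    ("C2", "C18"): 0.52, ("C2", "PC_aa_C32:0"): 0.22,
    ("C2", "PC_ae_C36:1"): 0.15, ("C2", "SM_C20:2"): -0.03,
    ("C5", "C8:1"): 0.02, ("C5", "C14"): 0.04, ("C5", "C18"): -0.12,
    ("C5", "PC_aa_C32:0"): -0.12, ("C5", "PC_ae_C36:1"): 0.02,
    ("C5", "SM_C20:2"): -0.11,
    ("C8:1", "C14"): 0.03, ("C8:1", "C18"): 0.09,
    ("C8:1", "PC_aa_C32:0"): 0.06, ("C8:1", "PC_ae_C36:1"): 0.06,
    ("C8:1", "SM_C20:2"): 0.00,
    ("C14", "C18"): 0.56, ("C14", "PC_aa_C32:0"): 0.03,
    ("C14", "PC_ae_C36:1"): 0.04, ("C14", "SM_C20:2"): 0.01,
    ("C18", "PC_aa_C32:0"): 0.01, ("C18", "PC_ae_C36:1"): 0.07,
    ("C18", "SM_C20:2"): -0.08,
    ("PC_aa_C32:0", "PC_ae_C36:1"): 0.84, ("PC_aa_C32:0", "SM_C20:2"): 0.86,
    ("PC_ae_C36:1", "SM_C20:2"): 0.75,
}


def phenotypic_correlations(traits: list[str] | None = None) -> pd.DataFrame:
    """Symmetric phenotypic correlation matrix for ``traits``.

    Pairs without a published value (e.g. involving ADG) default to 0.
    """
    if traits is None:
        traits = list(ANALYSIS_TRAITS)
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for (a, b), r in _PHENO_CORR_UPPER.items():
        if a in mat.index and b in mat.index:
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat


def nearest_psd_correlation(corr: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues below ``floor`` are clipped, then the diagonal is rescaled to
    one.  A matrix assembled from rounded printed values can be marginally
    indefinite; this guard keeps Cholesky factorisation valid.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh((corr + corr.T) / 2.0)
    if w.min() >= floor:
        return corr
    w = np.clip(w, floor, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed
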