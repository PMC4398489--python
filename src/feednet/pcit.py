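"""Partial correlation and information theory (PCIT) network inference.

PCIT flags gene-pair correlations that no third gene can explain away.  For
every trio of genes (x, y, z) the three first-order partial correlations are
computed, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

together with the trio's information-theoretic tolerance

    eps = (r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz) / 3,

the average ratio of partial to direct correlation.  The x-y association is
discarded if for at least one conditioning gene z both

    |r_xy| <= |eps * r_xz|   and   |r_xy| <= |eps * r_yz|

hold; associations never discarded by any z are significant.  The threshold
is thereby determined by the data rather than chosen a priori.

Ratio terms with an exactly zero direct correlation are omitted from the
trio mean (rather than propagating infinities); trios with a unit direct
correlation (degenerate denominator) are skipped and counted.

The implementation loops over the conditioning gene z and vectorises the
x-y plane, so cost is O(n^3) flops in O(n^2) memory; a thousand genes run on
an ordinary workstation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_ABS_PC = 0.80

#: correlations are clamped away from +-1 before entering the PC formula
_CLAMP = 1.0 - 1e-12


def gene_correlations(awm_values: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between gene rows across the trait columns."""
    values = awm_values.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 trait columns for row correlations")
    sd = values.std(axis=1)
    if (sd == 0).any():
        gene = awm_values.index[np.argmax(sd == 0)]
        raise ValueError(f"constant gene row {gene!r} has undefined correlations")
    corr = np.corrcoef(values)
    return pd.DataFrame(corr, index=awm_values.index, columns=awm_values.index)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y conditioning on z."""
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("conditioning correlations must have |r| < 1")
    return (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))


@dataclass
class PcitResult:
    correlations: pd.DataFrame
    significant: pd.DataFrame  # boolean, symmetric, False diagonal
    n_significant: int
    n_degenerate_trios: int

    def edge_frame(self) -> pd.DataFrame:
        """All significant unordered pairs with their correlation."""
        labels = self.correlations.index
        sig = self.significant.to_numpy()
        corr = self.correlations.to_numpy()
        iu = np.triu_indices(len(labels), k=1)
        mask = sig[iu]
        return pd.DataFrame(
            {
                "gene1": labels[iu[0][mask]],
                "gene2": labels[iu[1][mask]],
                "correlation": corr[iu][mask],
            }
        )


def run_pcit(corr: pd.DataFrame | np.ndarray) -> PcitResult:
    """Flag significant associations with the trio-tolerance rule.

    ``corr`` is a symmetric gene-gene Pearson correlation matrix.  Returns
    symmetric significance flags; deterministic.
    """
    if isinstance(corr, pd.DataFrame):
        labels = corr.index
        R = corr.to_numpy(dtype=float)
    else:
        R = np.asarray(corr, dtype=float)
        labels = pd.RangeIndex(len(R))
    n = R.shape[0]
    if n < 3:
        raise ValueError("PCIT needs at least 3 genes")
    if R.shape != (n, n) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    Rc = np.clip(R, -_CLAMP, _CLAMP)
    np.fill_diagonal(Rc, 1.0)
    absR = np.abs(R)
    discarded = np.zeros((n, n), dtype=bool)
    n_degenerate = 0
    idx = np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = Rc[z]  # r_xz as x varies
            # pc_xy.z over the x-y plane
            denom_z = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
            pc_xy_z = (Rc - np.outer(rz, rz)) / denom_z
            # pc_xz.y: conditioning on y, pair (x, z); x rows, y columns
            one_m_rxy2 = 1.0 - Rc**2
            denom_xz = np.sqrt(one_m_rxy2 * (1.0 - rz[None, :] ** 2))
            pc_xz_y = (rz[:, None] - Rc * rz[None, :]) / denom_xz
            # pc_yz.x: pair (y, z) conditioning on x; x rows, y columns
            denom_yz = np.sqrt(one_m_rxy2 * (1.0 - rz[:, None] ** 2))
            pc_yz_x = (rz[None, :] - Rc * rz[:, None]) / denom_yz

            # tolerance: mean of the partial/direct ratios, omitting terms
            # whose direct correlation is exactly zero
            ratios = np.zeros((n, n))
            counts = np.zeros((n, n))
            direct_xy = R
            direct_xz = R[:, z][:, None] * np.ones((1, n))
            direct_yz = R[z, :][None, :] * np.ones((n, 1))
            for pc, direct in (
                (pc_xy_z, direct_xy),
                (pc_xz_y, direct_xz),
                (pc_yz_x, direct_yz),
            ):
                ok = direct != 0.0
                ratios += np.where(ok, pc / np.where(ok, direct, 1.0), 0.0)
                counts += ok
            eps = np.where(counts > 0, ratios / np.where(counts > 0, counts, 1.0), 0.0)

            cond = (absR <= np.abs(eps * direct_xz)) & (
                absR <= np.abs(eps * direct_yz)
            )
            # degenerate trios: |r| = 1 in a conditioning pair -> skipped
            degen = (np.abs(direct_xz) >= 1.0) | (np.abs(direct_yz) >= 1.0)
            valid_pos = np.ones((n, n), dtype=bool)
            valid_pos[z, :] = False
            valid_pos[:, z] = False
            valid_pos[idx, idx] = False
            n_degenerate += int((degen & valid_pos).sum())
            discarded |= cond & valid_pos & ~degen
    significant = ~discarded
    significant &= significant.T
    significant[idx, idx] = False
    sig_df = pd.DataFrame(significant, index=labels, columns=labels)
    return PcitResult(
        correlations=corr if isinstance(corr, pd.DataFrame) else pd.DataFrame(R),
        significant=sig_df,
        n_significant=int(significant.sum() // 2),
        n_degenerate_trios=n_degenerate,
    )


def extract_edges(
    result: PcitResult, min_abs_pc: float = DEFAULT_MIN_ABS_PC,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Significant edges passing the |correlation| cut.

    Keeps unordered pairs that are PCIT-significant AND have an absolute
    correlation >= ``min_abs_pc`` (or > with ``inclusive=False``).  The
    reported edge weight is the direct correlation of the pair.  Genes with
    no surviving edge do not appear.
    """
    edges = result.edge_frame()
    mag = edges["correlation"].abs()
    keep = mag >= min_abs_pc if inclusive else mag > min_abs_pc
    return edges[keep].reset_index(drop=True)


def run_pcit_brute_force(corr: np.ndarray) -> np.ndarray:
    """Reference triple-loop PCIT used as an independent oracle in tests.

    Scalar arithmetic only; exponentially slower than :func:`run_pcit` and
    intended for n <= ~30.
    """
    R = np.asarray(corr, dtype=float)
    n = R.shape[0]
    Rc = np.clip(R, -_CLAMP, _CLAMP)
    discarded = np.zeros((n, n), dtype=bool)
    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                r_xy, r_xz, r_yz = R[x, y], R[x, z], R[y, z]
                if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
                    continue  # degenerate trio
                pc_xy = partial_correlation(Rc[x, y], Rc[x, z], Rc[y, z])
                pc_xz = partial_correlation(Rc[x, z], Rc[x, y], Rc[y, z])
                pc_yz = partial_correlation(Rc[y, z], Rc[x, y], Rc[x, z])
                terms = []
                if r_xy != 0.0:
                    terms.append(pc_xy / r_xy)
                if r_xz != 0.0:
                    terms.append(pc_xz / r_xz)
                if r_yz != 0.0:
                    terms.append(pc_yz / r_yz)
                eps = sum(terms) / len(terms) if terms else 0.0
                if abs(r_xy) <= abs(eps * r_xz) and abs(r_xy) <= abs(eps * r_yz):
                    discarded[x, y] = True
                    break
    sig = ~(discarded | discarded.T)
    np.fill_diagonal(sig, False)
    return sig
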