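"""Simpson turnover dissimilarity (βsim) between gridded assemblages.

For two cells with a shared species, b species private to the neighboring cell
and c species private to the focal cell, the Simpson turnover dissimilarity is

    βsim = min(b, c) / (a + min(b, c)) = 1 − a / (a + min(b, c)),

i.e. one minus the Simpson similarity a / (a + min(b, c)).  Identical or nested
assemblages score 0; disjoint assemblages score 1.

Because the index uses min(b, c), a nested assemblage pair (one species set
contained in the other) scores 0: βsim measures species *replacement* only and
is insensitive to richness differences — the property that makes it the
standard choice for delimiting biogeographic regions, where richness gradients
would otherwise masquerade as compositional boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import IncidenceMatrix


@dataclass(frozen=True)
class TurnoverMatrix:
    """Symmetric pairwise βsim dissimilarities over cells.

    ``d`` is an (n, n) float array with zero diagonal and values in [0, 1];
    ``components`` optionally retains the per-pair (a, b, c) species counts
    for diagnostics (b counts species private to the column cell, c species
    private to the row cell).
    """

    cell_ids: tuple[str, ...]
    d: np.ndarray
    components: dict | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.cell_ids)
        return pd.DataFrame(self.d, index=ids, columns=ids)

    def to_long(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (cell_i, cell_j, beta_sim)."""
        iu = np.triu_indices(self.n_cells, k=1)
        return pd.DataFrame(
            {
                "cell_i": [self.cell_ids[i] for i in iu[0]],
                "cell_j": [self.cell_ids[j] for j in iu[1]],
                "beta_sim": self.d[iu],
            }
        )


def beta_sim(x: set, y: set) -> float:
    """βsim between two species sets (both must be non-empty)."""
    if not x or not y:
        raise ValueError("beta_sim is undefined for empty assemblages")
    a = len(x & y)
    b = len(y - x)
    c = len(x - y)
    m = min(b, c)
    if a + m == 0:  # identical singletons etc.: no turnover
        return 0.0
    return m / (a + m)


def pairwise_turnover(
    m: IncidenceMatrix, keep_components: bool = False
) -> TurnoverMatrix:
    """βsim over all unordered cell pairs, vectorized over the 0/1 matrix.

    With occupancy matrix X, a = X Xᵀ and the private counts b, c follow from
    the row sums, so the full matrix costs one matrix product.  Raises if any
    cell is empty (drop such cells first: the index is undefined there).
    """
    occ = m.table.to_numpy(dtype=np.float64)
    rich = occ.sum(axis=1)
    if (rich == 0).any():
        empty = [cid for cid, r in zip(m.cell_ids, rich) if r == 0]
        raise ValueError(
            f"cells with no species: {empty}; apply drop_empty_cells first"
        )
    a = occ @ occ.T
    b = rich[None, :] - a  # species private to the column (neighboring) cell
    c = rich[:, None] - a  # species private to the row (focal) cell
    mn = np.minimum(b, c)
    d = mn / (a + mn + (a + mn == 0))  # denominator guard; a+mn=0 ⇒ mn=0 ⇒ d=0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # exact symmetry against fp noise
    components = None
    if keep_components:
        components = {"a": a.astype(int), "b": b.astype(int), "c": c.astype(int)}
    return TurnoverMatrix(tuple(m.cell_ids), d, components)


def write_turnover(t: TurnoverMatrix, square_path=None, long_path=None) -> None:
    if square_path is not None:
        t.to_frame().to_csv(square_path, index_label="cell_id")
    if long_path is not None:
        t.to_long().to_csv(long_path, index=False)
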