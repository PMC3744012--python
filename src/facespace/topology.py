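"""2-D cortical sheet geometry.

Neurons live on a rows x cols grid; lateral excitation couples each neuron to
its (up to) eight nearest grid neighbors. The sheet has hard edges — no
wraparound — so interior neurons have 8 neighbors, edge neurons 5 and corner
neurons 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridTopology"]


@dataclass(frozen=True)
class GridTopology:
    """8-neighborhood topology of a rectangular neuron sheet.

    Neuron ``(i, j)`` maps to flat index ``i * cols + j``. Neighbors of
    ``(i, j)`` are all on-grid cells ``(a, b)`` with ``i-1 <= a <= i+1`` and
    ``j-1 <= b <= j+1`` excluding ``(i, j)`` itself.
    """

    rows: int = 9
    cols: int = 9
    # padded (n, 8) neighbor index table; missing neighbors point at the
    # sentinel slot n, and counts holds the true neighbor count per neuron
    _index: np.ndarray = field(init=False, repr=False, compare=False)
    _counts: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        n = self.rows * self.cols
        index = np.full((n, 8), n, dtype=np.intp)
        counts = np.zeros(n, dtype=np.intp)
        for i in range(self.rows):
            for j in range(self.cols):
                flat = i * self.cols + j
                k = 0
                for a in (i - 1, i, i + 1):
                    for b in (j - 1, j, j + 1):
                        if (a, b) == (i, j):
                            continue
                        if 0 <= a < self.rows and 0 <= b < self.cols:
                            index[flat, k] = a * self.cols + b
                            k += 1
                counts[flat] = k
        index.setflags(write=False)
        counts.setflags(write=False)
        object.__setattr__(self, "_index", index)
        object.__setattr__(self, "_counts", counts)

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def neighbors(self, flat_index: int) -> np.ndarray:
        """Flat indices of the grid neighbors of one neuron."""
        k = self._counts[flat_index]
        return np.array(self._index[flat_index, :k])

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (row, col) per flat index."""
        rr, cc = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.column_stack([rr, cc])

    def neighbor_average(self, values: np.ndarray) -> np.ndarray:
        """Simple average of each neuron's neighbor values (edge-aware)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_neurons,):
            raise ValueError(
                f"expected {self.n_neurons} values, got shape {values.shape}"
            )
        padded = np.append(values, 0.0)
        return padded[self._index].sum(axis=1) / self._counts

    def neighbor_pairs(self) -> np.ndarray:
        """All unordered neighbor pairs (m, 2), each counted once."""
        n = self.n_neurons
        rows_, cols_ = np.nonzero(self._index < n)
        a = rows_
        b = self._index[rows_, cols_]
        keep = a < b
        return np.column_stack([a[keep], b[keep]])
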