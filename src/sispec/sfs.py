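"""Class-specific unfolded site frequency spectra.

The polymorphism side of the analysis is carried by a single container: for a
haploid sample of size ``n``, the expected number of segregating sites with
derived-allele count ``j`` (j = 1..n-1) in each of three mutation classes —
strong-to-weak (``S>W``: G/C ancestral, A/T derived), weak-to-strong (``W>S``)
and GC-conservative (``neutral``: W>W or S>S) — together with the numbers of
surveyed sites whose ancestral state is weak (``L_W``) or strong (``L_S``).

Entries may be fractional: probabilistic ancestral-state inference spreads a
segregating site across the two possible orientations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mutation classes, in canonical order.
CLASSES = ("S>W", "W>S", "neutral")

#: Opposite orientation of each class (a misoriented S>W site looks W>S and
#: vice versa; a GC-conservative site stays GC-conservative).
OPPOSITE = {"S>W": "W>S", "W>S": "S>W", "neutral": "neutral"}

STRONG = frozenset("GC")
WEAK = frozenset("AT")


def mutation_class(ancestral: str, derived: str) -> str:
    """W/S mutation class of an ancestral -> derived change."""
    a_strong = ancestral in STRONG
    d_strong = derived in STRONG
    if a_strong and not d_strong:
        return "S>W"
    if not a_strong and d_strong:
        return "W>S"
    return "neutral"


@dataclass
class ClassSFS:
    """Unfolded SFS per mutation class plus surveyed site totals.

    Parameters
    ----------
    n:
        Haploid sample size.
    xi:
        Mapping class -> array of length ``n - 1``; ``xi[c][j - 1]`` is the
        (possibly fractional) number of segregating sites of class ``c`` with
        derived count ``j``.
    L_W, L_S:
        Surveyed numbers of ancestrally weak (A/T) and strong (G/C) sites;
        the denominators of the per-site mutation-rate contrasts.
    n_sites:
        Total number of analyzed sites; defaults to ``L_W + L_S``.
    """

    n: int
    xi: dict[str, np.ndarray]
    L_W: float
    L_S: float
    n_sites: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        for c in CLASSES:
            if c not in self.xi:
                raise ValueError(f"missing SFS class {c!r}")
            arr = np.asarray(self.xi[c], dtype=float)
            if arr.shape != (self.n - 1,):
                raise ValueError(
                    f"class {c!r}: expected {self.n - 1} entries, got {arr.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"class {c!r}: negative SFS entries")
            self.xi[c] = arr
        if self.L_W < 0 or self.L_S < 0:
            raise ValueError("site totals must be non-negative")
        if self.n_sites is None:
            self.n_sites = self.L_W + self.L_S

    @property
    def j(self) -> np.ndarray:
        """Derived-allele counts 1..n-1."""
        return np.arange(1, self.n)

    def total_segregating(self, cls: str | None = None) -> float:
        if cls is not None:
            return float(self.xi[cls].sum())
        return float(sum(self.xi[c].sum() for c in CLASSES))

    @property
    def n_monomorphic(self) -> float:
        return float(self.n_sites) - self.total_segregating()

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"class": c, "j": int(j), "xi": float(x)}
            for c in CLASSES
            for j, x in zip(self.j, self.xi[c])
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# n={self.n}\tL_W={self.L_W!r}\tL_S={self.L_S!r}"
                f"\tn_sites={self.n_sites!r}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClassSFS":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing ClassSFS header line")
            meta = dict(
                kv.split("=", 1) for kv in header.lstrip("#").strip().split("\t")
            )
            frame = pd.read_csv(io.StringIO(fh.read()), sep="\t")
        n = int(meta["n"])
        xi = {}
        for c in CLASSES:
            sub = frame[frame["class"] == c].set_index("j")["xi"]
            xi[c] = sub.reindex(range(1, n), fill_value=0.0).to_numpy(float)
        return cls(
            n=n,
            xi=xi,
            L_W=float(meta["L_W"]),
            L_S=float(meta["L_S"]),
            n_sites=float(meta["n_sites"]),
        )


def zero_sfs(n: int, L_W: float = 0.0, L_S: float = 0.0) -> ClassSFS:
    """An empty spectrum, convenient as an accumulator."""
    return ClassSFS(
        n=n, xi={c: np.zeros(n - 1) for c in CLASSES}, L_W=L_W, L_S=L_S, n_sites=L_W + L_S
    )
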