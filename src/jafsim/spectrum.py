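"""Allele-frequency-spectrum containers, folding, text I/O and summary statistics.

A joint allele-frequency spectrum (jAFS) for samples of ``n1`` and ``n2``
haploid genomes is an ``(n1+1) x (n2+1)`` array whose cell ``(i, j)`` counts
SNPs at which the derived (or, after folding, minor) allele was observed
``i`` times in population 1 and ``j`` times in population 2.  The two
"monomorphic" corners ``(0, 0)`` and ``(n1, n2)`` carry no information about
polymorphism and are always masked.  One-dimensional spectra (single
population) use the same container with shape ``(n+1,)``.

The text format read and written here is the whitespace-separated format of
dadi/moments: a header line with the shape, a ``folded``/``unfolded`` flag and
optional population labels, one line of flattened values, and one line of
0/1 mask entries.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Spectrum",
    "JointAFS",
    "fold",
    "read_sfs",
    "write_sfs",
    "pi_from_afs",
    "dxy_from_jafs",
    "fst_from_jafs",
    "MonomorphicSpectrumError",
]


class MonomorphicSpectrumError(ValueError):
    """Raised when a statistic is undefined because the spectrum has no
    usable polymorphism (e.g. the between-population heterozygosity used to
    normalise F_ST is zero)."""


def _default_mask(shape: tuple[int, ...]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[(0,) * len(shape)] = True
    mask[tuple(s - 1 for s in shape)] = True
    return mask


def _fold_mask(shape: tuple[int, ...]) -> np.ndarray:
    """Mask for cells whose total derived count exceeds half the sample."""
    tot = sum(s - 1 for s in shape)
    counts = np.zeros(shape)
    for axis, s in enumerate(shape):
        idx = [None] * len(shape)
        idx[axis] = slice(None)
        counts = counts + np.arange(s)[tuple(idx)]
    return counts > tot / 2.0


class Spectrum:
    """An (joint) allele-frequency spectrum.

    Parameters
    ----------
    data:
        Array of shape ``(n1+1,)`` or ``(n1+1, n2+1)``.  Counts (integers)
        or expected densities (floats).
    folded:
        Whether the spectrum indexes minor-allele counts (folded) rather
        than derived-allele counts.
    mask:
        Boolean array of masked (unusable) cells.  The monomorphic corners
        are always added to whatever is passed; for folded spectra the
        upper triangle (total count > n/2) is masked as well.
    """

    def __init__(self, data, folded: bool = False, mask=None):
        self.data = np.array(data, dtype=float, copy=True)
        if self.data.ndim not in (1, 2):
            raise ValueError("spectrum must be 1-D or 2-D")
        self.folded = bool(folded)
        m = _default_mask(self.data.shape)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")
            m = m | mask
        if self.folded:
            m = m | _fold_mask(self.data.shape)
        self.mask = m
        self.data[self.mask] = 0.0

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s - 1 for s in self.data.shape)

    def sum(self) -> float:
        """Total mass over unmasked cells (number of SNPs in counts mode)."""
        return float(self.data[~self.mask].sum())

    # segregating sites, spelled the way population geneticists say it
    S = sum

    def copy(self) -> "Spectrum":
        return Spectrum(self.data.copy(), folded=self.folded, mask=self.mask.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "folded" if self.folded else "unfolded"
        return f"Spectrum(shape={self.shape}, {kind}, S={self.sum():.6g})"

    def allclose(self, other: "Spectrum", **kw) -> bool:
        return (
            self.shape == other.shape
            and self.folded == other.folded
            and bool(np.array_equal(self.mask, other.mask))
            and bool(np.allclose(self.data, other.data, **kw))
        )

    # -- folding -------------------------------------------------------------
    def fold(self) -> "Spectrum":
        """Fold onto minor-allele counts (by *total* derived-allele count).

        Cell ``(i, j)`` with ``i + j > (n1 + n2) / 2`` is added to its
        complement ``(n1 - i, n2 - j)``; cells exactly at half the total
        sample size are averaged with their complement.  Folding a folded
        spectrum is a no-op.
        """
        if self.folded:
            return self.copy()
        shape = self.data.shape
        tot = sum(s - 1 for s in shape)
        counts = np.zeros(shape)
        for axis, s in enumerate(shape):
            idx = [None] * len(shape)
            idx[axis] = slice(None)
            counts = counts + np.arange(s)[tuple(idx)]
        rev = self.data[tuple(slice(None, None, -1) for _ in shape)]
        rev_mask = self.mask[tuple(slice(None, None, -1) for _ in shape)]
        where_fold = counts > tot / 2.0
        tie = counts == tot / 2.0
        folded = np.where(where_fold, 0.0, self.data + np.where(rev_mask, 0.0, rev))
        folded = np.where(tie, (self.data + rev) / 2.0, folded)
        return Spectrum(folded, folded=True, mask=self.mask & ~where_fold)


#: The two-population spectrum used throughout the package.
JointAFS = Spectrum


def fold(afs: Spectrum) -> Spectrum:
    """Functional alias for :meth:`Spectrum.fold`."""
    return afs.fold()


# ---------------------------------------------------------------------------
# dadi/moments SFS text format
# ---------------------------------------------------------------------------

def write_sfs(afs: Spectrum, path, pop_ids: tuple[str, ...] | None = None) -> None:
    """Write a spectrum in the dadi/moments plain-text SFS format."""
    with open(path, "w") as fh:
        dims = " ".join(str(s) for s in afs.shape)
        flag = "folded" if afs.folded else "unfolded"
        header = f"{dims} {flag}"
        if pop_ids:
            header += " " + " ".join(f'"{p}"' for p in pop_ids)
        fh.write(header + "\n")
        fh.write(" ".join(repr(float(v)) for v in afs.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in afs.mask.ravel()) + "\n")


def read_sfs(path) -> Spectrum:
    """Read a spectrum written by :func:`write_sfs` (dadi/moments format).

    Raises ``ValueError`` with an informative message on malformed input.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected header, data and mask lines")
    header = lines[0].split()
    dims: list[int] = []
    rest: list[str] = []
    for tok in header:
        if not rest:
            try:
                dims.append(int(tok))
                continue
            except ValueError:
                pass
        rest.append(tok)
    if not dims or len(dims) > 2:
        raise ValueError(f"{path}: header must start with 1 or 2 integer dimensions")
    folded = False
    for tok in rest:
        low = tok.lower().strip('"')
        if low == "folded":
            folded = True
        elif low == "unfolded":
            folded = False
    size = int(np.prod(dims))
    try:
        data = np.array([float(v) for v in lines[1].split()])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric spectrum entry ({exc})") from None
    if data.size != size:
        raise ValueError(
            f"{path}: header promises {size} entries, data line has {data.size}"
        )
    if np.any(data < 0):
        raise ValueError(f"{path}: negative spectrum entries")
    mask = None
    if len(lines) >= 3:
        mask_vals = lines[2].split()
        if len(mask_vals) != size:
            raise ValueError(f"{path}: mask line has {len(mask_vals)} of {size} entries")
        mask = np.array([v not in ("0", "0.0") for v in mask_vals]).reshape(dims)
    return Spectrum(data.reshape(dims), folded=folded, mask=mask)


# ---------------------------------------------------------------------------
# AFS-based summary statistics
# ---------------------------------------------------------------------------

def pi_from_afs(afs) -> float:
    """Nucleotide diversity from a 1-D spectrum.

    pi = sum_i [2 i (n - i) / (n (n - 1))] xi_i.  The coefficient is
    symmetric under i -> n - i, so the statistic is invariant to folding.
    Accepts a :class:`Spectrum` or a raw array of length n+1.
    """
    if not isinstance(afs, Spectrum):
        afs = Spectrum(afs)
    if afs.ndim != 1:
        raise ValueError("pi_from_afs expects a 1-D spectrum")
    n = afs.shape[0] - 1
    if n < 2:
        raise ValueError("need a sample size of at least 2")
    i = np.arange(n + 1)
    coef = 2.0 * i * (n - i) / (n * (n - 1.0))
    vals = np.where(afs.mask, 0.0, afs.data)
    return float((coef * vals).sum())


def _between_coeffs(shape):
    n1, n2 = shape[0] - 1, shape[1] - 1
    i = np.arange(n1 + 1)[:, None] / n1
    j = np.arange(n2 + 1)[None, :] / n2
    return i * (1.0 - j) + j * (1.0 - i)


def dxy_from_jafs(jafs: Spectrum) -> float:
    """Absolute divergence d_xy summed over the cells of a jAFS.

    d_xy = sum_{ij} [p_i (1 - q_j) + q_j (1 - p_i)] c_ij, with p = i/n1 and
    q = j/n2.  Symmetric under joint relabelling of alleles, hence valid for
    folded spectra too.
    """
    if jafs.ndim != 2:
        raise ValueError("dxy_from_jafs expects a 2-D spectrum")
    vals = np.where(jafs.mask, 0.0, jafs.data)
    return float((_between_coeffs(jafs.shape) * vals).sum())


def fst_from_jafs(jafs: Spectrum) -> float:
    """Hudson-type F_ST computed from a jAFS as a ratio of averages.

    F_ST = 1 - Hw / Hb where Hw is the mean within-population heterozygosity
    (average of the two populations) and Hb the mean between-population
    heterozygosity (the d_xy summand), both summed over cells before taking
    the ratio.  Raises :class:`MonomorphicSpectrumError` when Hb is zero.
    """
    if jafs.ndim != 2:
        raise ValueError("fst_from_jafs expects a 2-D spectrum")
    n1, n2 = jafs.sample_sizes
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two haploid samples per population")
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    hw1 = 2.0 * i * (n1 - i) / (n1 * (n1 - 1.0))
    hw2 = 2.0 * j * (n2 - j) / (n2 * (n2 - 1.0))
    hw = (hw1 + hw2) / 2.0
    hb = _between_coeffs(jafs.shape)
    vals = np.where(jafs.mask, 0.0, jafs.data)
    num = float((hw * vals).sum())
    den = float((hb * vals).sum())
    if den <= 0.0:
        raise MonomorphicSpectrumError(
            "between-population heterozygosity is zero; F_ST undefined"
        )
    return 1.0 - num / den
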