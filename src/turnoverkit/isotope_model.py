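"""Peptide elemental compositions and isotopologue envelopes.

The observable in a metabolic-labeling MS experiment is the isotopologue
envelope of a peptide: the relative-abundance vector over nominal mass
offsets 0, 1, 2, ... above the monoisotopic species.  Two envelopes matter
here:

* the *natural* envelope, fixed by terrestrial isotope abundances of
  C/H/N/O/S, which describes pre-existing ("old") protein; and
* the *labeled* envelope of protein synthesized from a free-leucine pool in
  which a fraction ``p`` of leucine carries three deuteriums, so each of a
  peptide's ``L`` leucines independently shifts the envelope by +3 nominal
  offsets with probability ``p``.

Residue compositions and isotope abundances are shipped as TSV data files
next to this module and can be overridden for testing or for non-standard
isotope tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ElementalComposition",
    "IsotopeTable",
    "composition_from_sequence",
    "count_label_sites",
    "natural_envelope",
    "labeled_envelope",
    "default_isotope_table",
    "load_residue_table",
    "HEAVY_LEUCINE_OFFSET",
]

ELEMENTS = ("C", "H", "N", "O", "S")

#: Nominal mass offset contributed by one [5,5,5-2H3]-leucine residue.
HEAVY_LEUCINE_OFFSET = 3


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts for C, H, N, O, S of an intact (neutral) peptide."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative atom count for {el}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            *(getattr(self, el) + getattr(other, el) for el in ELEMENTS)
        )

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope distributions over nominal mass offsets.

    ``distributions[element]`` is a tuple of ``(offset, abundance)`` pairs
    with strictly increasing integer offsets whose abundances sum to 1.
    """

    distributions: dict[str, tuple[tuple[int, float], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for el, pairs in self.distributions.items():
            offsets = [o for o, _ in pairs]
            if any(o < 0 for o in offsets):
                raise ValueError(f"{el}: negative isotope offset")
            if offsets != sorted(set(offsets)):
                raise ValueError(f"{el}: offsets must be strictly increasing")
            total = sum(a for _, a in pairs)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{el}: abundances sum to {total!r}, not 1")

    def distribution_vector(self, element: str) -> np.ndarray:
        """Dense abundance vector indexed by nominal offset."""
        pairs = self.distributions[element]
        vec = np.zeros(pairs[-1][0] + 1)
        for off, ab in pairs:
            vec[off] = ab
        return vec


_RESIDUE_TABLE_CACHE: dict[str, dict[str, ElementalComposition]] = {}

# Composition removed by each peptide-bond condensation, and the terminal
# H / OH restored on the intact peptide.
_WATER = ElementalComposition(H=2, O=1)


def load_residue_table(path: str | None = None) -> dict[str, ElementalComposition]:
    """Load residue (amino acid minus water) compositions from TSV."""
    key = path or "<default>"
    if key in _RESIDUE_TABLE_CACHE:
        return _RESIDUE_TABLE_CACHE[key]
    if path is None:
        text = (
            resources.files("turnoverkit.data")
            .joinpath("residue_composition.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    table: dict[str, ElementalComposition] = {}
    for line in lines[1:]:
        fields = dict(zip(header, line.split("\t")))
        table[fields["residue"]] = ElementalComposition(
            *(int(fields[el]) for el in ELEMENTS)
        )
    _RESIDUE_TABLE_CACHE[key] = table
    return table


@lru_cache(maxsize=None)
def default_isotope_table(path: str | None = None) -> IsotopeTable:
    """IUPAC terrestrial isotope abundances for C, H, N, O, S."""
    if path is None:
        text = (
            resources.files("turnoverkit.data")
            .joinpath("isotope_abundance.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    dists: dict[str, list[tuple[int, float]]] = {}
    for line in lines[1:]:
        el, off, ab = line.split("\t")
        dists.setdefault(el, []).append((int(off), float(ab)))
    return IsotopeTable({el: tuple(pairs) for el, pairs in dists.items()})


def composition_from_sequence(
    sequence: str, residue_table: dict[str, ElementalComposition] | None = None
) -> ElementalComposition:
    """Elemental composition of the intact peptide (N-terminal H, C-terminal OH).

    Raises ``ValueError`` naming the first residue letter that is not one of
    the 20 standard one-letter codes.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = residue_table if residue_table is not None else load_residue_table()
    comp = _WATER  # terminal H + OH
    for ch in sequence:
        if ch not in table:
            raise ValueError(f"unknown residue {ch!r} in sequence {sequence!r}")
        comp = comp + table[ch]
    return comp


def count_label_sites(sequence: str) -> int:
    """Number of leucines (heavy-label sites).  Isoleucine does not count."""
    composition_from_sequence(sequence)  # validates
    return sequence.count("L")


def _convolve_truncated(a: np.ndarray, b: np.ndarray, max_len: int) -> np.ndarray:
    return np.convolve(a, b)[:max_len]


def _element_power(dist: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """dist ** n under truncated convolution, by binary exponentiation."""
    result = np.zeros(1)
    result[0] = 1.0
    base = dist[:max_len]
    while n:
        if n & 1:
            result = _convolve_truncated(result, base, max_len)
        base = _convolve_truncated(base, base, max_len)
        n >>= 1
    return result


def natural_envelope(
    composition: ElementalComposition,
    max_offset: int,
    isotope_table: IsotopeTable | None = None,
) -> np.ndarray:
    """Natural-abundance isotopologue envelope, truncated and renormalized.

    Entry 0 is the monoisotopic species.  The envelope is the convolution of
    every atom's isotope distribution; after truncation at ``max_offset`` the
    vector is renormalized to sum to 1.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    table = isotope_table or default_isotope_table()
    max_len = max_offset + 1
    env = np.zeros(max_len)
    env[0] = 1.0
    for el in ELEMENTS:
        n = getattr(composition, el)
        if n == 0:
            continue
        env = _convolve_truncated(env, _element_power(table.distribution_vector(el), n, max_len), max_len)
    if env.size < max_len:
        env = np.pad(env, (0, max_len - env.size))
    total = env.sum()
    if total <= 0:
        raise ValueError("envelope truncated to zero mass")
    return env / total


def default_max_offset(n_label_sites: int) -> int:
    """Default envelope width: 3 offsets per label site plus 6 for natural mass."""
    return HEAVY_LEUCINE_OFFSET * n_label_sites + 6


@lru_cache(maxsize=200_000)
def _cached_natural(sequence: str, max_offset: int) -> np.ndarray:
    nat = natural_envelope(composition_from_sequence(sequence), max_offset)
    nat.setflags(write=False)
    return nat


def _labeled_from_natural(nat: np.ndarray, L: int, p: float) -> np.ndarray:
    """Binomial mixture of 3-offset shifts of a precomputed natural envelope."""
    if L == 0 or p == 0.0:
        return nat
    max_offset = nat.size - 1
    env = np.zeros(nat.size)
    for h in range(L + 1):
        shift = HEAVY_LEUCINE_OFFSET * h
        if shift > max_offset:
            break
        env[shift:] += _binom_pmf(h, L, p) * nat[: nat.size - shift]
    return env / env.sum()


def mixture_basis(sequence: str, p: float, max_offset: int | None = None):
    """(natural, labeled) envelope pair for a peptide.

    The expensive natural-envelope convolution is cached per sequence; the
    labeled envelope is assembled from it per call, which keeps sweeps over
    the enrichment parameter cheap.
    """
    L = sequence.count("L")  # residues validated by the cached natural envelope
    if max_offset is None:
        max_offset = default_max_offset(L)
    nat = _cached_natural(sequence, max_offset)
    return nat, _labeled_from_natural(nat, L, float(p))


def labeled_envelope(
    sequence: str,
    p: float,
    max_offset: int | None = None,
    isotope_table: IsotopeTable | None = None,
) -> np.ndarray:
    """Envelope of a peptide synthesized entirely from a pool at enrichment ``p``.

    Each of the ``L`` leucines is heavy with probability ``p`` independently,
    shifting the natural envelope by ``3h`` offsets with binomial weight
    ``C(L,h) p^h (1-p)^(L-h)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"enrichment p={p} outside [0, 1]")
    L = count_label_sites(sequence)
    if max_offset is None:
        max_offset = default_max_offset(L)
    nat = natural_envelope(composition_from_sequence(sequence), max_offset, isotope_table)
    if L == 0:
        return nat
    # Binomial mixture over the number of heavy leucines.
    weights = np.zeros(L + 1)
    for h in range(L + 1):
        weights[h] = _binom_pmf(h, L, p)
    env = np.zeros(max_offset + 1)
    for h in range(L + 1):
        shift = HEAVY_LEUCINE_OFFSET * h
        if shift > max_offset:
            break
        width = max_offset + 1 - shift
        env[shift:] += weights[h] * nat[:width]
    total = env.sum()
    return env / total


def _binom_pmf(h: int, L: int, p: float) -> float:
    from math import comb

    return comb(L, h) * p**h * (1.0 - p) ** (L - h)
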