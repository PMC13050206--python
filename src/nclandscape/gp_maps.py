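"""Genotype-phenotype (GP) map models and tabular I/O.

A GP map assigns every length-``L`` string over a ``K``-letter alphabet
exactly one categorical phenotype label.  One designated label marks the
*deleterious* phenotype, which is pinned to fitness zero downstream and
excluded from neutral-component analysis.  Maps may additionally restrict
which point mutations are allowed; the restriction must be symmetric so
that the induced mutation graph is undirected.

Two generative models are built in:

* :class:`FibonacciGPMap` — the phenotype is the genotype prefix before the
  first occurrence of a stop letter; genotypes without a stop letter are
  deleterious.
* :class:`LowEvolvabilityFibonacciGPMap` — same phenotype rule, but the
  first stop letter cannot mutate and no mutation may introduce a stop
  letter before the first one, which lowers phenotypic evolvability while
  preserving neutral-component sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "GPMap",
    "FibonacciGPMap",
    "LowEvolvabilityFibonacciGPMap",
    "TabularGPMap",
    "GenotypeSpaceTooLargeError",
    "GPMapTableError",
    "enumerate_genotypes",
    "mutational_neighbors",
    "read_gp_map_table",
    "write_gp_map_table",
]

DEFAULT_DELETERIOUS_LABEL = "DELETERIOUS"
DEFAULT_SIZE_CAP = 10**8


class GenotypeSpaceTooLargeError(ValueError):
    """Raised when K**L exceeds the configured enumeration cap."""


class GPMapTableError(ValueError):
    """Base class for errors while parsing tabular GP maps."""


class InconsistentLengthError(GPMapTableError):
    pass


class DuplicateGenotypeError(GPMapTableError):
    pass


class MissingGenotypeError(GPMapTableError):
    pass


class AlphabetInferenceError(GPMapTableError):
    pass


@dataclass(frozen=True)
class GPMap:
    """Base GP-map contract.

    Parameters
    ----------
    alphabet :
        Ordered tuple of ``K`` distinct single characters.
    length :
        Sequence length ``L``.
    deleterious_label :
        Phenotype label designating the zero-fitness class.
    """

    alphabet: tuple[str, ...]
    length: int
    deleterious_label: str = DEFAULT_DELETERIOUS_LABEL

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must contain at least 2 characters")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet characters must be distinct")
        for ch in self.alphabet:
            if len(ch) != 1:
                raise ValueError(f"alphabet entries must be single characters, got {ch!r}")

    @property
    def K(self) -> int:
        return len(self.alphabet)

    @property
    def L(self) -> int:
        return self.length

    @property
    def n_genotypes(self) -> int:
        return self.K**self.L

    def phenotype_of(self, genotype: str) -> str:
        raise NotImplementedError

    def is_deleterious(self, genotype: str) -> bool:
        return self.phenotype_of(genotype) == self.deleterious_label

    def mutation_allowed(self, genotype: str, position: int, new_letter: str) -> bool:
        """Whether substituting ``new_letter`` at 0-based ``position`` is allowed.

        The default is unrestricted point mutation.  Implementations must keep
        the relation symmetric: ``allowed(g -> g')`` iff ``allowed(g' -> g)``.
        """
        self._check_mutation_args(genotype, position, new_letter)
        return True

    def _check_mutation_args(self, genotype: str, position: int, new_letter: str) -> None:
        if len(genotype) != self.length:
            raise ValueError(f"genotype {genotype!r} has length {len(genotype)}, expected {self.length}")
        if not 0 <= position < self.length:
            raise ValueError(f"position {position} out of range for L={self.length}")
        if new_letter not in self.alphabet:
            raise ValueError(f"letter {new_letter!r} not in alphabet {self.alphabet}")

    def validate_genotype(self, genotype: str) -> None:
        if len(genotype) != self.length:
            raise ValueError(f"genotype {genotype!r} has length {len(genotype)}, expected {self.length}")
        for ch in genotype:
            if ch not in self.alphabet:
                raise ValueError(f"character {ch!r} of {genotype!r} not in alphabet {self.alphabet}")


@dataclass(frozen=True)
class FibonacciGPMap(GPMap):
    """Stop-codon prefix model.

    The phenotype of a genotype is its prefix strictly before the first
    occurrence of ``stop_letter``; genotypes with no stop letter are
    deleterious.  The empty prefix (stop letter in first position) is a
    valid, non-deleterious phenotype.  All point mutations are allowed.
    """

    alphabet: tuple[str, ...] = ("0", "1", "2")
    length: int = 12
    stop_letter: str = "2"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.stop_letter not in self.alphabet:
            raise ValueError(f"stop letter {self.stop_letter!r} must be in the alphabet {self.alphabet}")

    def phenotype_of(self, genotype: str) -> str:
        self.validate_genotype(genotype)
        idx = genotype.find(self.stop_letter)
        if idx < 0:
            return self.deleterious_label
        return genotype[:idx]

    def first_stop_index(self, genotype: str) -> int:
        """0-based index of the first stop letter; ``L`` if none occurs."""
        idx = genotype.find(self.stop_letter)
        return idx if idx >= 0 else self.length


@dataclass(frozen=True)
class LowEvolvabilityFibonacciGPMap(FibonacciGPMap):
    """Fibonacci model with restricted mutations.

    A substitution is forbidden iff (a) it hits the first stop letter, or
    (b) it introduces a stop letter strictly before the first stop letter.
    Genotypes without a stop letter have first-stop index ``L``, so rule (b)
    prevents them from ever gaining one; this is the only convention that
    keeps the mutation relation symmetric.
    """

    def mutation_allowed(self, genotype: str, position: int, new_letter: str) -> bool:
        self._check_mutation_args(genotype, position, new_letter)
        first_stop = self.first_stop_index(genotype)
        if position == first_stop:
            return False
        if position < first_stop and new_letter == self.stop_letter:
            return False
        return True


@dataclass(frozen=True)
class TabularGPMap(GPMap):
    """GP map backed by an explicit genotype -> phenotype dictionary."""

    table: dict[str, str] = field(default_factory=dict)

    def phenotype_of(self, genotype: str) -> str:
        try:
            return self.table[genotype]
        except KeyError:
            raise KeyError(f"genotype {genotype!r} not present in the tabular GP map") from None

    @classmethod
    def from_dict(
        cls,
        table: dict[str, str],
        deleterious_label: str = DEFAULT_DELETERIOUS_LABEL,
        alphabet: Sequence[str] | None = None,
        fill_missing: bool = False,
    ) -> "TabularGPMap":
        """Build a complete tabular map from a dictionary.

        With ``fill_missing`` the genotypes absent from ``table`` are assigned
        the deleterious label; otherwise the table must cover all K**L strings.
        """
        if not table:
            raise GPMapTableError("empty GP-map table")
        lengths = {len(g) for g in table}
        if len(lengths) != 1:
            raise InconsistentLengthError(f"genotypes of multiple lengths present: {sorted(lengths)}")
        (L,) = lengths
        if alphabet is None:
            chars = sorted({ch for g in table for ch in g})
            if len(chars) < 2:
                raise AlphabetInferenceError(
                    f"cannot infer an alphabet of size >= 2 from the table (saw {chars})"
                )
            alphabet = chars
        alphabet = tuple(alphabet)
        full = dict(table)
        for g in ("".join(t) for t in itertools.product(alphabet, repeat=L)):
            if g not in full:
                if fill_missing:
                    full[g] = deleterious_label
                else:
                    raise MissingGenotypeError(f"genotype {g!r} missing from the table (strict mode)")
        return cls(alphabet=alphabet, length=L, deleterious_label=deleterious_label, table=full)


def enumerate_genotypes(gp_map: GPMap, size_cap: int = DEFAULT_SIZE_CAP) -> Iterator[str]:
    """Yield all K**L genotypes in lexicographic order of the alphabet.

    Raises :class:`GenotypeSpaceTooLargeError` if K**L exceeds ``size_cap``.
    """
    n = gp_map.n_genotypes
    if n > size_cap:
        raise GenotypeSpaceTooLargeError(
            f"K={gp_map.K}, L={gp_map.L} gives {n} genotypes, above the cap of {size_cap}"
        )
    for tup in itertools.product(gp_map.alphabet, repeat=gp_map.length):
        yield "".join(tup)


def mutational_neighbors(genotype: str, gp_map: GPMap) -> list[str]:
    """All single-substitution neighbors permitted by ``mutation_allowed``.

    For unrestricted maps this yields exactly (K-1)*L genotypes.
    """
    gp_map.validate_genotype(genotype)
    out: list[str] = []
    for pos, current in enumerate(genotype):
        for letter in gp_map.alphabet:
            if letter == current:
                continue
            if gp_map.mutation_allowed(genotype, pos, letter):
                out.append(genotype[:pos] + letter + genotype[pos + 1 :])
    return out


def read_gp_map_table(
    path: str | Path,
    deleterious_label: str = DEFAULT_DELETERIOUS_LABEL,
    strict: bool = True,
    header: bool = False,
) -> TabularGPMap:
    """Read a two-column genotype TAB phenotype TSV into a :class:`TabularGPMap`.

    In strict mode all K**L genotypes over the inferred alphabet must be
    listed; in lenient mode missing genotypes are assigned the deleterious
    label.  Duplicate rows with conflicting phenotypes are an error.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if header else None,
        names=["genotype", "phenotype"],
        dtype=str,
        keep_default_na=False,
    )
    table: dict[str, str] = {}
    for g, p in zip(df["genotype"], df["phenotype"]):
        if g in table and table[g] != p:
            raise DuplicateGenotypeError(
                f"genotype {g!r} listed with conflicting phenotypes {table[g]!r} and {p!r}"
            )
        table[g] = p
    return TabularGPMap.from_dict(
        table, deleterious_label=deleterious_label, fill_missing=not strict
    )


def write_gp_map_table(gp_map: GPMap, path: str | Path, header: bool = False) -> None:
    """Write a GP map as a two-column TSV in lexicographic genotype order."""
    rows = ((g, gp_map.phenotype_of(g)) for g in enumerate_genotypes(gp_map))
    df = pd.DataFrame(rows, columns=["genotype", "phenotype"])
    df.to_csv(path, sep="\t", index=False, header=header)
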