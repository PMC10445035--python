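"""Data model for deterministic and non-deterministic genotype-phenotype maps.

A genotype space is the set of all strings of a fixed length ``L`` over a
finite ordered alphabet of size ``K``; every genotype has exactly
``(K - 1) * L`` point-mutation (Hamming distance 1) neighbours.  A
*deterministic* GP map assigns one phenotype label per genotype
(many-to-one).  A *non-deterministic* (ND) GP map assigns each genotype a
probability distribution over phenotype labels (many-to-many) -- for RNA,
the Boltzmann distribution over suboptimal secondary structures.

Phenotype labels are opaque strings throughout: dot-bracket structures,
abstract shapes or arbitrary tokens are all handled identically.
"""

from __future__ import annotations

import math
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field

from .errors import InvalidGenotypeError, MapValidationError

#: Tolerance on |sum of probabilities - 1| accepted when validating a
#: per-genotype phenotype distribution.
PROBABILITY_TOLERANCE = 1e-9

RNA_ALPHABET = ("A", "C", "G", "U")
BINARY_ALPHABET = ("0", "1")


@dataclass(frozen=True)
class GenotypeSpace:
    """The set of all length-``length`` strings over ``alphabet``.

    Parameters
    ----------
    alphabet
        Ordered, duplicate-free symbols (single characters). The order fixes
        genotype ranks and the neighbour iteration order.
    length
        Number of positions per genotype, ``L >= 1``.
    """

    alphabet: tuple[str, ...]
    length: int
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        alphabet = tuple(self.alphabet)
        if len(alphabet) < 2:
            raise ValueError("alphabet must contain at least 2 symbols")
        if len(set(alphabet)) != len(alphabet):
            raise ValueError("alphabet symbols must be unique")
        if any(len(a) != 1 for a in alphabet):
            raise ValueError("alphabet symbols must be single characters")
        if self.length < 1:
            raise ValueError("genotype length must be >= 1")
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(alphabet)})

    @property
    def K(self) -> int:
        return len(self.alphabet)

    @property
    def size(self) -> int:
        """Number of genotypes in the space, ``K**L``."""
        return self.K**self.length

    @property
    def neighbors_per_genotype(self) -> int:
        """Point-mutation neighbourhood size, ``(K - 1) * L`` (``3L`` for RNA)."""
        return (self.K - 1) * self.length

    def validate_genotype(self, genotype: str) -> None:
        if len(genotype) != self.length:
            raise InvalidGenotypeError(
                f"genotype {genotype!r} has length {len(genotype)}, expected {self.length}"
            )
        for symbol in genotype:
            if symbol not in self._index:
                raise InvalidGenotypeError(
                    f"genotype {genotype!r} contains symbol {symbol!r} "
                    f"outside alphabet {''.join(self.alphabet)!r}"
                )

    def neighbors(self, genotype: str) -> list[str]:
        """All point-mutation neighbours of ``genotype`` (itself excluded).

        Returned in a fixed order (position-major, alphabet-minor); the
        result has exactly ``(K - 1) * L`` distinct elements.
        """
        self.validate_genotype(genotype)
        out = []
        for pos, symbol in enumerate(genotype):
            prefix, suffix = genotype[:pos], genotype[pos + 1 :]
            for other in self.alphabet:
                if other != symbol:
                    out.append(prefix + other + suffix)
        return out

    def genotypes(self) -> Iterator[str]:
        """Iterate over all genotypes in rank (lexicographic) order."""
        for rank in range(self.size):
            yield self.unrank(rank)

    def rank(self, genotype: str) -> int:
        """Integer rank of a genotype in [0, K**L), alphabet-lexicographic."""
        self.validate_genotype(genotype)
        r = 0
        for symbol in genotype:
            r = r * self.K + self._index[symbol]
        return r

    def unrank(self, rank: int) -> str:
        if not 0 <= rank < self.size:
            raise ValueError(f"rank {rank} outside [0, {self.size})")
        chars = []
        for _ in range(self.length):
            rank, d = divmod(rank, self.K)
            chars.append(self.alphabet[d])
        return "".join(reversed(chars))


def point_mutation_neighbors(genotype: str, space: GenotypeSpace) -> list[str]:
    """Point-mutation neighbours of ``genotype`` in ``space``.

    Free-function alias of :meth:`GenotypeSpace.neighbors`.
    """
    return space.neighbors(genotype)


def rna_space(length: int) -> GenotypeSpace:
    return GenotypeSpace(RNA_ALPHABET, length)


class PhenotypeDistribution(Mapping):
    """A probability distribution over phenotype labels for one genotype.

    The support contains only phenotypes with strictly positive probability
    and the probabilities sum to 1 within :data:`PROBABILITY_TOLERANCE`.
    ``dist[p]`` returns 0.0 for phenotypes outside the support, matching the
    convention P(p|g) = 0.
    """

    __slots__ = ("_probs",)

    def __init__(self, probabilities: Mapping[str, float], *, renormalize: bool = False):
        probs = {p: float(w) for p, w in probabilities.items() if w != 0.0}
        if not probs:
            raise MapValidationError("phenotype distribution is empty")
        if any(w < 0.0 for w in probs.values()):
            raise MapValidationError("phenotype probabilities must be positive")
        total = math.fsum(probs.values())
        if renormalize:
            probs = {p: w / total for p, w in probs.items()}
        elif abs(total - 1.0) > PROBABILITY_TOLERANCE:
            raise MapValidationError(
                f"phenotype probabilities sum to {total!r}, not 1 "
                f"(tolerance {PROBABILITY_TOLERANCE})"
            )
        self._probs = probs

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self._probs)

    def __getitem__(self, phenotype: str) -> float:
        return self._probs.get(phenotype, 0.0)

    def get(self, phenotype: str, default: float = 0.0) -> float:
        return self._probs.get(phenotype, default)

    def __iter__(self):
        return iter(self._probs)

    def __len__(self):
        return len(self._probs)

    def __contains__(self, phenotype) -> bool:
        return phenotype in self._probs

    def items(self):
        return self._probs.items()

    def argmax(self) -> str:
        """Most probable phenotype; ties broken by smallest label.

        This is the deterministic-projection rule ("most frequent structure
        in the ensemble"), made reproducible by lexicographic tie-breaking.
        """
        return min(self._probs, key=lambda p: (-self._probs[p], p))

    def is_point_mass(self) -> bool:
        return len(self._probs) == 1

    def __repr__(self):
        inner = ", ".join(f"{p!r}: {w:.6g}" for p, w in sorted(self._probs.items()))
        return f"PhenotypeDistribution({{{inner}}})"

    def __eq__(self, other):
        if isinstance(other, PhenotypeDistribution):
            return self._probs == other._probs
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._probs.items()))


def point_mass(phenotype: str) -> PhenotypeDistribution:
    return PhenotypeDistribution({phenotype: 1.0})


class NDGPMap:
    """A non-deterministic GP map: genotype -> phenotype distribution.

    Parameters
    ----------
    space
        The genotype space the map lives in.
    table
        One :class:`PhenotypeDistribution` per genotype.  For a *complete*
        map the table covers all ``K**L`` genotypes; a map declared over a
        genotype sample carries ``complete=False`` and per-sample semantics
        apply downstream (see the estimators module).
    complete
        Whether the table covers the whole space.  Inferred from the table
        size by default.
    """

    def __init__(
        self,
        space: GenotypeSpace,
        table: Mapping[str, PhenotypeDistribution],
        *,
        complete: bool | None = None,
        validate: bool = True,
    ):
        self.space = space
        self.table: dict[str, PhenotypeDistribution] = dict(table)
        if not self.table:
            raise MapValidationError("ND GP map has no genotypes")
        if validate:
            bad = []
            for g, dist in self.table.items():
                try:
                    space.validate_genotype(g)
                except InvalidGenotypeError:
                    bad.append(g)
                    continue
                if not isinstance(dist, PhenotypeDistribution):
                    raise TypeError(f"table value for {g!r} is not a PhenotypeDistribution")
            if bad:
                raise MapValidationError("invalid genotypes in map", offenders=bad)
        if complete is None:
            complete = len(self.table) == space.size
        elif complete and len(self.table) != space.size:
            raise MapValidationError(
                f"map declared complete but covers {len(self.table)} of {space.size} genotypes"
            )
        self.complete: bool = complete
        self._universe: tuple[str, ...] | None = None

    def __len__(self):
        return len(self.table)

    def __contains__(self, genotype) -> bool:
        return genotype in self.table

    def distribution(self, genotype: str) -> PhenotypeDistribution:
        try:
            return self.table[genotype]
        except KeyError:
            raise InvalidGenotypeError(f"genotype {genotype!r} not in map") from None

    def probability(self, phenotype: str, genotype: str) -> float:
        """P(p|g); 0.0 when ``phenotype`` is outside the genotype's ensemble."""
        return self.distribution(genotype)[phenotype]

    @property
    def phenotype_universe(self) -> tuple[str, ...]:
        """All phenotypes appearing in any ensemble, sorted; its size is N-tilde."""
        if self._universe is None:
            seen: set[str] = set()
            for dist in self.table.values():
                seen.update(dist.support)
            self._universe = tuple(sorted(seen))
        return self._universe

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotype_universe)

    def neutral_set(self, phenotype: str) -> set[str]:
        """ND neutral set: genotypes whose ensemble contains ``phenotype``."""
        return {g for g, dist in self.table.items() if phenotype in dist}

    def is_point_mass(self) -> bool:
        return all(dist.is_point_mass() for dist in self.table.values())


class DGPMap:
    """A deterministic GP map: genotype -> single phenotype."""

    def __init__(
        self,
        space: GenotypeSpace,
        table: Mapping[str, str],
        *,
        complete: bool | None = None,
        validate: bool = True,
    ):
        self.space = space
        self.table: dict[str, str] = dict(table)
        if not self.table:
            raise MapValidationError("deterministic GP map has no genotypes")
        if validate:
            bad = []
            for g in self.table:
                try:
                    space.validate_genotype(g)
                except InvalidGenotypeError:
                    bad.append(g)
            if bad:
                raise MapValidationError("invalid genotypes in map", offenders=bad)
        if complete is None:
            complete = len(self.table) == space.size
        self.complete: bool = complete
        self._phenotypes: tuple[str, ...] | None = None

    def __len__(self):
        return len(self.table)

    def __contains__(self, genotype) -> bool:
        return genotype in self.table

    def phenotype(self, genotype: str) -> str:
        try:
            return self.table[genotype]
        except KeyError:
            raise InvalidGenotypeError(f"genotype {genotype!r} not in map") from None

    @property
    def phenotypes(self) -> tuple[str, ...]:
        """Distinct phenotypes, sorted; its size is the deterministic count N."""
        if self._phenotypes is None:
            self._phenotypes = tuple(sorted(set(self.table.values())))
        return self._phenotypes

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def neutral_set(self, phenotype: str) -> set[str]:
        return {g for g, p in self.table.items() if p == phenotype}

    def as_nd(self) -> NDGPMap:
        """View as an ND map of point masses (exact embedding)."""
        return NDGPMap(
            self.space,
            {g: point_mass(p) for g, p in self.table.items()},
            complete=self.complete,
            validate=False,
        )


def project_deterministic(nd: NDGPMap) -> DGPMap:
    """Deterministic projection: each genotype's most probable phenotype.

    Ties are broken by the lexicographically smallest phenotype label, so
    the projection is reproducible.  This mirrors taking the MFE (most
    probable) structure as the deterministic phenotype of an RNA sequence.
    """
    return DGPMap(
        nd.space,
        {g: dist.argmax() for g, dist in nd.table.items()},
        complete=nd.complete,
        validate=False,
    )
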