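"""RNA thermodynamic backend: ND GP maps from Boltzmann suboptimal ensembles.

Each sequence is folded into its complete set of suboptimal secondary
structures within an energy window above the minimum free energy (default
15 k_B T), via the ViennaRNA suboptimal-enumeration routine.  The unfolded
(open-chain) structure is always part of the ensemble, with characteristic
free energy G = 0.0 kcal/mol, even when it falls outside the window.
Structure probabilities are Boltzmann weights exp(-G_p / kT) renormalized
over the retained set.

Shape-level coarse-graining (the RNAshapes30 protocol) aggregates the
structure probabilities per level-2 abstract shape; isolated base pairs are
disabled for that backend, matching the published protocol.

The engine's own constants supply kT (GASCONST at the configured
temperature); nothing thermodynamic is hard-coded here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

from .core import NDGPMap, PhenotypeDistribution, rna_space
from .errors import FoldingBackendError
from .shapes import OPEN_CHAIN_SHAPE, abstract_shape

try:  # the ViennaRNA python bindings
    import RNA as _RNA
except ImportError:  # pragma: no cover - engine present in supported setups
    _RNA = None

__all__ = [
    "FoldConfig",
    "EnsembleRecord",
    "thermal_energy",
    "boltzmann_ensemble",
    "ensemble_record",
    "shape_ensemble",
    "fold_function",
    "build_rna_map",
    "build_rna12_map",
    "build_shapes_map",
    "engine_version",
]


def _require_engine():
    if _RNA is None:
        raise FoldingBackendError(
            "the ViennaRNA python bindings are required for the RNA backend"
        )
    return _RNA


def engine_version() -> str:
    return _require_engine().__version__


def thermal_energy(temperature_c: float = 37.0) -> float:
    """k_B T in kcal/mol at ``temperature_c``, from the engine's constants."""
    RNA = _require_engine()
    return RNA.GASCONST / 1000.0 * (RNA.K0 + temperature_c)


@dataclass(frozen=True)
class FoldConfig:
    """Folding configuration.

    ``window_kbt`` is the suboptimal energy range above the MFE in units of
    k_B T; ``shape_level`` of ``None`` keeps dot-bracket phenotypes, an
    integer 1-5 coarse-grains to abstract shapes; ``no_lonely_pairs``
    disables isolated base pairs (the shapes protocol).
    """

    temperature_c: float = 37.0
    window_kbt: float = 15.0
    shape_level: int | None = None
    no_lonely_pairs: bool = False

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature_c)

    def provenance(self) -> dict:
        return {
            "engine": f"ViennaRNA {engine_version()}",
            "temperature_c": self.temperature_c,
            "window_kbt": self.window_kbt,
            "shape_level": self.shape_level,
            "no_lonely_pairs": int(self.no_lonely_pairs),
        }


#: The RNAshapes30 protocol: level-2 shapes, no isolated base pairs.
SHAPES_CONFIG = FoldConfig(shape_level=2, no_lonely_pairs=True)


@dataclass
class EnsembleRecord:
    """The raw Boltzmann ensemble of one sequence.

    ``structures`` lists (dot-bracket, free energy kcal/mol) for every
    retained suboptimal structure including the open chain;
    ``ensemble_free_energy`` is G_ens = -kT ln Z over the full partition
    function; ``retained_mass`` is the Boltzmann mass of the retained set
    relative to the full ensemble (the renormalization records what was
    truncated).
    """

    sequence: str
    structures: list[tuple[str, float]]
    ensemble_free_energy: float
    kT: float
    window_kbt: float
    retained_mass: float


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    if not seq or any(c not in "ACGU" for c in seq):
        raise FoldingBackendError(f"invalid RNA sequence {sequence!r}")
    return seq


def _subopt_structures(seq: str, config: FoldConfig) -> list[tuple[str, float]]:
    RNA = _require_engine()
    md = RNA.md()
    md.temperature = config.temperature_c
    md.uniq_ML = 1
    if config.no_lonely_pairs:
        md.noLP = 1
    try:
        fc = RNA.fold_compound(seq, md)
        delta = int(round(config.window_kbt * config.kT * 100.0))
        solutions = fc.subopt(delta)
    except Exception as exc:  # engine-level failure
        raise FoldingBackendError(f"folding failed for {seq!r}: {exc}") from exc
    # energies are on a 0.01 kcal/mol grid; round away float32 noise
    structures = [(s.structure, round(s.energy, 2)) for s in solutions]
    open_chain = "." * len(seq)
    if not any(db == open_chain for db, _ in structures):
        # the unfolded state is always retained, at G = 0.0 kcal/mol
        structures.append((open_chain, 0.0))
    return structures


def _boltzmann_probs(structures: list[tuple[str, float]], kT: float) -> list[float]:
    emin = min(e for _, e in structures)
    weights = [math.exp(-(e - emin) / kT) for _, e in structures]
    z = math.fsum(weights)
    return [w / z for w in weights]


def boltzmann_ensemble(sequence: str, config: FoldConfig = FoldConfig()) -> PhenotypeDistribution:
    """Boltzmann distribution over suboptimal dot-bracket structures.

    All structures within ``window_kbt * kT`` of the MFE plus the open
    chain, with probabilities renormalized over the retained set.
    """
    seq = _validate_sequence(sequence)
    structures = _subopt_structures(seq, config)
    probs = _boltzmann_probs(structures, config.kT)
    return PhenotypeDistribution(
        {db: p for (db, _), p in zip(structures, probs)}, renormalize=True
    )


def ensemble_record(sequence: str, config: FoldConfig = FoldConfig()) -> EnsembleRecord:
    """Full ensemble bookkeeping for one sequence (includes G_ens via the
    partition function, and the retained Boltzmann mass)."""
    RNA = _require_engine()
    seq = _validate_sequence(sequence)
    structures = sorted(_subopt_structures(seq, config), key=lambda se: (se[1], se[0]))
    kT = config.kT
    md = RNA.md()
    md.temperature = config.temperature_c
    if config.no_lonely_pairs:
        md.noLP = 1
    fc = RNA.fold_compound(seq, md)
    _, mfe = fc.mfe()
    fc.exp_params_rescale(mfe)
    _, g_ens = fc.pf()
    retained = math.fsum(math.exp((g_ens - e) / kT) for _, e in structures)
    return EnsembleRecord(seq, structures, g_ens, kT, config.window_kbt, retained)


def shape_ensemble(
    sequence: str, level: int = 2, config: FoldConfig = SHAPES_CONFIG
) -> PhenotypeDistribution:
    """Boltzmann ensemble aggregated into abstract shape classes.

    Structure probabilities are summed within each shape class; the
    unfolded state maps to the open-chain shape ``"_"``.
    """
    seq = _validate_sequence(sequence)
    structures = _subopt_structures(seq, config)
    probs = _boltzmann_probs(structures, config.kT)
    by_shape: dict[str, float] = {}
    for (db, _), p in zip(structures, probs):
        shape = abstract_shape(db, level)
        by_shape[shape] = by_shape.get(shape, 0.0) + p
    return PhenotypeDistribution(by_shape, renormalize=True)


def fold_function(config: FoldConfig = FoldConfig()):
    """A genotype -> PhenotypeDistribution callable for the estimators."""
    if config.shape_level is None:
        return lambda seq: boltzmann_ensemble(seq, config)
    return lambda seq: shape_ensemble(seq, config.shape_level, config)


# ---------------------------------------------------------------------------
# map builders


def build_rna_map(
    length: int,
    config: FoldConfig = FoldConfig(),
    *,
    tsv_path=None,
    checkpoint_every: int = 50_000,
    progress: bool = False,
) -> NDGPMap:
    """Exhaustive ND GP map over all 4**length RNA sequences.

    With ``tsv_path`` the map is streamed to disk in the GP-map TSV dialect
    as it is built and the build is resumable: a ``<tsv_path>.progress``
    sidecar records the next genotype rank, and a restarted call appends
    from there.  Expect hours of CPU for length 12; lengths <= 10 are
    desk-scale.
    """
    space = rna_space(length)
    fold = fold_function(config)
    label_cache: dict[str, str] = {}

    def fold_shared(seq: str) -> PhenotypeDistribution:
        # share label strings across rows to keep big maps compact
        dist = fold(seq)
        return PhenotypeDistribution(
            {label_cache.setdefault(p, p): w for p, w in dist.items()}, renormalize=True
        )

    def maybe_progress(it):
        if progress:  # pragma: no cover - cosmetic
            try:
                from tqdm import tqdm
            except ImportError:
                return it
            return tqdm(it, total=space.size)
        return it

    if tsv_path is None:
        table = {space.unrank(r): fold_shared(space.unrank(r)) for r in maybe_progress(range(space.size))}
        return NDGPMap(space, table, complete=True, validate=False)

    # streamed, resumable build: fold only from the checkpointed rank on,
    # append rows, then load the finished map back from disk
    tsv_path = Path(tsv_path)
    progress_path = Path(str(tsv_path) + ".progress")
    if tsv_path.exists() and progress_path.exists():
        start_rank = int(progress_path.read_text().strip())
        fh = tsv_path.open("a", encoding="utf-8", newline="\n")
    else:
        start_rank = 0
        fh = tsv_path.open("w", encoding="utf-8", newline="\n")
        fh.write(f"#ndgpmap v1 alphabet=ACGU L={length}\n")
        for key, value in config.provenance().items():
            fh.write(f"# {key}={value}\n")
        progress_path.write_text("0")
    with fh:
        for rank in maybe_progress(range(start_rank, space.size)):
            seq = space.unrank(rank)
            dist = fold_shared(seq)
            for p in sorted(dist.support):
                fh.write(f"{seq}\t{p}\t{dist[p]!r}\n")
            if (rank + 1) % checkpoint_every == 0:
                fh.flush()
                progress_path.write_text(str(rank + 1))
    progress_path.write_text(str(space.size))
    from .io import read_ndmap

    return read_ndmap(tsv_path, complete=True)


def build_rna12_map(config: FoldConfig = FoldConfig(), **kwargs) -> NDGPMap:
    """The full RNA12 ND GP map (4**12 = 16,777,216 sequences; hours of CPU)."""
    return build_rna_map(12, config, **kwargs)


def build_shapes_map(
    sequences,
    level: int = 2,
    config: FoldConfig = SHAPES_CONFIG,
) -> NDGPMap:
    """Sampled ND GP map over abstract shapes for the given sequences.

    ``sequences`` may be a :class:`~ndgpmap.estimators.SequenceSample` or an
    iterable of equal-length RNA strings.  The result is a declared sample
    (``complete=False``); estimator semantics apply downstream.
    """
    seqs = list(getattr(sequences, "sequences", sequences))
    if not seqs:
        raise FoldingBackendError("no sequences supplied")
    space = rna_space(len(seqs[0]))
    config = replace(config, shape_level=level)
    fold = fold_function(config)
    table = {seq: fold(seq) for seq in dict.fromkeys(seqs)}
    return NDGPMap(space, table, complete=False, validate=True)
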