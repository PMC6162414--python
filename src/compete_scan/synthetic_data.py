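"""Synthetic inputs: null transcripts, random regulators, planted fixtures.

Everything the test-suite and the validation experiments consume is
generated here, deterministically per seed: i.i.d. background transcripts,
Dirichlet random motifs, random miRNAs, and transcripts with engineered
(miRNA site, RBP site) co-occurrences whose coordinates are recorded in a
truth table. Plants overwrite background bases in place (the transcript
length is fixed), so truth-table coordinates are exact.

The background model is 0-order (independent bases); real lncRNA
composition statistics beyond mononucleotide frequencies are deliberately
not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mirna_scan import MiRNA, mirna_type_ddg, reverse_complement
from .rbp_scan import MotifModel
from .sequence_io import RNA_ALPHABET, NamedSequence

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


def random_transcript(
    length: int,
    composition=_UNIFORM,
    seed: int = 0,
    name: str = "transcript",
) -> NamedSequence:
    """i.i.d. random transcript with the given base composition (A,C,G,U)."""
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("composition must be 4 non-negative values summing to 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    bases = rng.choice(list(RNA_ALPHABET), size=length, p=comp)
    return NamedSequence(name, "".join(bases))


def random_mirna(length: int = 22, seed: int = 0, name: str = "mir") -> MiRNA:
    """Uniform random mature miRNA of the given length (>= 8 nt)."""
    if length < 8:
        raise ValueError("mature miRNA length must be >= 8")
    rng = np.random.default_rng(seed)
    mature = "".join(rng.choice(list(RNA_ALPHABET), size=length))
    return MiRNA(name, mature)


def random_motif(
    k: int = 8,
    concentration: float = 0.5,
    seed: int = 0,
    name: str = "rbp",
) -> MotifModel:
    """Random PFM with columns drawn from a symmetric Dirichlet.

    Low concentration gives sharp, informative motifs (columns close to a
    single base); concentration 1 is flat on the simplex.
    """
    if k < 3:
        raise ValueError("motif width must be >= 3")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    pfm = rng.dirichlet([concentration] * 4, size=k)
    return MotifModel(name, pfm)


def motif_from_consensus(
    word: str, name: str = "rbp", sharpness: float = 0.94
) -> MotifModel:
    """Sharp motif whose consensus is exactly ``word``.

    The consensus base gets probability ``sharpness`` at each position; the
    rest is split evenly. At the default sharpness a full-length consensus
    match passes any reasonable p-value cutoff for k >= 4.
    """
    if not 0.25 < sharpness < 1:
        raise ValueError("sharpness must be in (0.25, 1)")
    rows = []
    off = (1 - sharpness) / 3
    for c in word:
        row = [off] * 4
        row[RNA_ALPHABET.index(c)] = sharpness
        rows.append(row)
    return MotifModel(name, np.array(rows))


@dataclass(frozen=True)
class Plant:
    """One engineered co-occurrence: an 8mer miRNA site plus a motif site.

    ``offset`` is the transcript coordinate of the miRNA site start; the
    motif consensus is placed ``gap`` bases after the miRNA site end
    (negative gap = overlap; overlapping letters must agree).
    """

    mirna: MiRNA
    motif: MotifModel
    offset: int
    gap: int


@dataclass(frozen=True)
class FixtureSpec:
    length: int
    plants: tuple[Plant, ...]
    composition: tuple[float, ...] = _UNIFORM
    seed: int = 0
    name: str = "fixture"


def plant_fixture(
    spec: FixtureSpec,
) -> tuple[NamedSequence, list[MiRNA], list[MotifModel], pd.DataFrame]:
    """Background transcript with the spec's planted site pairs.

    Returns the transcript, the distinct miRNAs and motifs involved, and a
    truth table of planted coordinates (0-based half-open). Raises on
    out-of-bounds plants and on collisions (two plants demanding different
    letters at one position).
    """
    background = random_transcript(
        spec.length, spec.composition, spec.seed, spec.name
    )
    chars = list(background.sequence)
    required: dict[int, str] = {}
    rows = []

    def write(start: int, word: str, what: str) -> None:
        if start < 0 or start + len(word) > spec.length:
            raise ValueError(
                f"{what} at [{start},{start + len(word)}) falls outside the "
                f"{spec.length} nt transcript"
            )
        for i, c in enumerate(word):
            pos = start + i
            if pos in required and required[pos] != c:
                raise ValueError(
                    f"plant collision at position {pos}: "
                    f"{required[pos]!r} vs {c!r} ({what})"
                )
            required[pos] = c
            chars[pos] = c

    for plant in spec.plants:
        site8 = reverse_complement(plant.mirna.seed) + "A"
        write(plant.offset, site8, f"miRNA site ({plant.mirna.name})")
        rbp_start = plant.offset + len(site8) + plant.gap
        write(rbp_start, plant.motif.consensus,
              f"motif site ({plant.motif.rbp_name})")
        rows.append(
            {
                "mirna": plant.mirna.name,
                "rbp": plant.motif.rbp_name,
                "mirna_start": plant.offset,
                "mirna_end": plant.offset + len(site8),
                "rbp_start": rbp_start,
                "rbp_end": rbp_start + plant.motif.k,
                "gap": plant.gap,
            }
        )

    mirnas, motifs = [], []
    for plant in spec.plants:
        if plant.mirna.name not in {m.name for m in mirnas}:
            mirnas.append(plant.mirna)
        if plant.motif.rbp_name not in {m.rbp_name for m in motifs}:
            motifs.append(plant.motif)
    transcript = NamedSequence(spec.name, "".join(chars))
    return transcript, mirnas, motifs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presets


def _stable_mirna(seed: int, name: str, max_ddg: float = -7.0) -> MiRNA:
    """Random miRNA whose full seed duplex is comfortably stable.

    Resamples until the 7-pair duplex ddG is at or below ``max_ddg`` so
    that planted 8mer sites survive the default energetic cutoff of
    -6 kcal/mol with margin.
    """
    for attempt in range(200):
        mir = random_mirna(22, seed=seed * 1000 + attempt, name=name)
        if mirna_type_ddg(mir)["8mer"] <= max_ddg:
            return mir
    raise RuntimeError("could not sample a stable miRNA seed")


def power_fixture(
    seed: int,
    length: int = 2000,
    n_plants: int = 10,
    n_decoys: int = 2,
    k: int = 8,
) -> tuple[NamedSequence, list[MiRNA], list[MotifModel], pd.DataFrame]:
    """Planted-overlap power fixture: one (motif, miRNA) pair, many events.

    ``n_plants`` exact-overlap events (the motif site shares its first base,
    an A, with the terminal A of the 8mer miRNA site: gap = -1) are spaced
    evenly along an i.i.d. background of ``length`` nt, plus ``n_decoys``
    unplanted miRNAs and motifs.
    """
    rng = np.random.default_rng(seed)
    mir = _stable_mirna(seed, "mir-planted")
    consensus = "A" + "".join(rng.choice(list(RNA_ALPHABET), size=k - 1))
    motif = motif_from_consensus(consensus, "RBP-planted")
    span = 8 - 1 + k  # footprint of one planted event
    step = (length - 2 * span) // n_plants
    if step < span + 2:
        raise ValueError("transcript too short for the requested plants")
    plants = tuple(
        Plant(mir, motif, offset=span + i * step, gap=-1)
        for i in range(n_plants)
    )
    transcript, mirnas, motifs, truth = plant_fixture(
        FixtureSpec(length=length, plants=plants, seed=seed, name="power")
    )
    for j in range(n_decoys):
        mirnas.append(random_mirna(22, seed=seed * 7919 + j, name=f"mir-decoy{j}"))
        motifs.append(
            random_motif(k, concentration=0.2, seed=seed * 104729 + j,
                         name=f"RBP-decoy{j}")
        )
    return transcript, mirnas, motifs, truth


def calibration_inputs(
    seed: int,
    n_transcripts: int = 200,
    length: int = 1000,
    n_motifs: int = 5,
    n_mirnas: int = 5,
    k: int = 8,
    concentration: float = 0.2,
) -> tuple[list[NamedSequence], list[MiRNA], list[MotifModel]]:
    """Unplanted null inputs for type-I error calibration.

    i.i.d. uniform transcripts with random sharp motifs and random miRNAs;
    nothing is enriched, so permutation p-values should be uniform up to
    the discreteness of the co-occurrence counts.
    """
    transcripts = [
        random_transcript(length, seed=seed * 100003 + i, name=f"null{i}")
        for i in range(n_transcripts)
    ]
    motifs = [
        random_motif(k, concentration, seed=seed * 15485863 + j, name=f"RBP{j}")
        for j in range(n_motifs)
    ]
    mirnas = [
        random_mirna(22, seed=seed * 32452843 + j, name=f"mir{j}")
        for j in range(n_mirnas)
    ]
    return transcripts, mirnas, motifs


def landscape_fixture(
    seed: int,
    n_transcripts: int = 16,
    shared_in: int = 6,
    min_length: int = 800,
    length_step: int = 200,
    events_per_pair: int = 5,
    k: int = 8,
):
    """Multi-transcript fixture for census/correlation summaries.

    One shared (miRNA, motif) pair is planted in ``shared_in`` transcripts
    spread across the length range (every other transcript, so shared
    plants do not concentrate plant density at one end). Every transcript
    additionally carries its own private pairs — one distinct pair per
    ~500 nt of length, each planted ``events_per_pair`` times — so that
    the number of genuinely co-occurring pairs grows with transcript
    length, as it does for real transcript collections. Returns
    (transcripts, mirnas, motifs, truth tables per transcript).
    """
    rng = np.random.default_rng(seed)
    shared_mir = _stable_mirna(seed + 1, "mir-shared")
    shared_motif = motif_from_consensus(
        "A" + "".join(rng.choice(list(RNA_ALPHABET), size=k - 1)), "RBP-shared"
    )
    shared_hosts = {2 * i for i in range(shared_in)}
    if max(shared_hosts, default=0) >= n_transcripts:
        raise ValueError("shared_in must be <= n_transcripts / 2")
    transcripts, truths = [], []
    mirnas = {shared_mir.name: shared_mir}
    motifs = {shared_motif.rbp_name: shared_motif}
    span = 8 - 1 + k
    for t in range(n_transcripts):
        length = min_length + length_step * t
        pairs = []
        if t in shared_hosts:
            pairs.append((shared_mir, shared_motif))
        for j in range(max(1, length // 500)):
            mir = _stable_mirna(seed * 131 + t * 17 + j + 2, f"mir-t{t}p{j}")
            motif = motif_from_consensus(
                "A" + "".join(rng.choice(list(RNA_ALPHABET), size=k - 1)),
                f"RBP-t{t}p{j}",
            )
            mirnas[mir.name] = mir
            motifs[motif.rbp_name] = motif
            pairs.append((mir, motif))
        n_slots = events_per_pair * len(pairs)
        step = (length - 2 * span) // n_slots
        if step < span + 2:
            raise ValueError("transcript too short for the requested plants")
        plants = []
        pos = span
        for _ in range(events_per_pair):
            for mir, motif in pairs:
                plants.append(Plant(mir, motif, offset=pos, gap=-1))
                pos += step
        transcript, _, _, truth = plant_fixture(
            FixtureSpec(
                length=length, plants=tuple(plants),
                seed=seed * 613 + t, name=f"lnc{t}",
            )
        )
        transcripts.append(transcript)
        truths.append(truth)
    return transcripts, list(mirnas.values()), list(motifs.values()), truths
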