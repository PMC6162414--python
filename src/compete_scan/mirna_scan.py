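"""miRNA target-site scanning by canonical seed matching.

The seed is bases 2-8 of the mature miRNA (1-based, 5'->3'). A target site
is an occurrence, on the transcript strand, of the reverse complement of the
seed (or of its 6-nt core), classified into the four canonical site types:

========  =============================================================
8mer      full 7-nt seed match followed by an A on the transcript
7mer-m8   full 7-nt seed match (pairing at mature position 8)
7mer-A1   6-nt core match followed by an A on the transcript
6mer      6-nt core match (pairing at mature positions 2-7)
========  =============================================================

Only Watson-Crick pairing is considered; G:U wobbles do not count as seed
matches. Each transcript locus (one occurrence of the 6-nt core) is
reported once, with the highest-priority type it supports among the
requested types (8mer > 7mer-m8 > 7mer-A1 > 6mer).

An optional energetic score in the spirit of PITA's ddG accompanies each
site: the seed:target duplex free energy from nearest-neighbor stacking
parameters (see :func:`ddg_score`), with the structure-opening term set to
zero. More negative means more stable; sites are filtered at a ddG cutoff
when the scan mode requests it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .sequence_io import RNA_ALPHABET, NamedSequence

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
# higher value = higher priority when one locus supports several types
_PRIORITY = {t: i for i, t in enumerate(reversed(SITE_TYPES))}

SCAN_MODES = ("seed_only", "energy", "intersection", "union")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _load_stack_table() -> dict[str, float]:
    ref = resources.files("compete_scan.data") / "nn_stacking.json"
    return json.loads(ref.read_text())["stacks"]


#: Nearest-neighbor stacking dG37 (kcal/mol) keyed by 5'->3' dinucleotide step.
STACKING_DG = _load_stack_table()


def derive_seed(mirna_mature: str) -> str:
    """Return the 7-nt seed: bases 2-8 (1-based) of the mature strand."""
    if len(mirna_mature) < 8:
        raise ValueError(
            f"mature miRNA must be >= 8 nt, got {len(mirna_mature)}"
        )
    return mirna_mature[1:8]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA with its derived 7-nt seed (mature bases 2-8)."""

    name: str
    mature: str
    seed: str = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.mature) - set(RNA_ALPHABET)
        if bad:
            raise ValueError(f"miRNA {self.name!r}: non-RNA characters {bad}")
        object.__setattr__(self, "seed", derive_seed(self.mature))

    @classmethod
    def from_sequence(cls, named: NamedSequence) -> "MiRNA":
        return cls(named.name, named.sequence)


@dataclass(frozen=True)
class SeedMatchSite:
    """A seed-match site in 0-based half-open transcript coordinates."""

    mirna_name: str
    start: int
    end: int
    site_type: str
    ddg: float | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
        if self.end - self.start != expected[self.site_type]:
            raise ValueError(
                f"{self.site_type} site must span {expected[self.site_type]} "
                f"bases, got [{self.start},{self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ScanParams:
    """Run configuration for the scanning and evaluation stages.

    Defaults follow the published pipeline: 5000 shuffle permutations,
    RBP site p-value cutoff 0.01, ddG cutoff -6 kcal/mol, distance 0
    (sites must share at least one base) and FDR cutoff 0.05.
    """

    ddg_cutoff: float = -6.0
    rbp_pvalue_cutoff: float = 0.01
    distance: int = 0
    site_types: tuple[str, ...] = SITE_TYPES
    mode: str = "energy"
    n_permutations: int = 5000
    fdr_cutoff: float = 0.05
    base_seed: int = 1
    preserve_dinucleotides: bool = False
    pvalue_correction: bool = False  # (K+1)/(N+1) instead of K/N

    def __post_init__(self) -> None:
        if not 0 <= self.distance <= 100:
            raise ValueError("distance must be in [0, 100] bases")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mode not in SCAN_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {SCAN_MODES}")
        unknown = set(self.site_types) - set(SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types {unknown}")
        if not self.site_types:
            raise ValueError("site_types must be non-empty")
        if not 0 < self.rbp_pvalue_cutoff <= 1:
            raise ValueError("rbp_pvalue_cutoff must be in (0, 1]")
        if not 0 < self.fdr_cutoff <= 1:
            raise ValueError("fdr_cutoff must be in (0, 1]")


def stringent_params(**overrides) -> ScanParams:
    """The stringent profile: p <= 0.01, ddG <= -6, distance 0, FDR <= 0.05."""
    base = dict(
        rbp_pvalue_cutoff=0.01,
        ddg_cutoff=-6.0,
        distance=0,
        fdr_cutoff=0.05,
        mode="energy",
    )
    base.update(overrides)
    return ScanParams(**base)


def scan_seed_sites(
    transcript: NamedSequence,
    mirna: MiRNA,
    site_types: tuple[str, ...] | set[str] = SITE_TYPES,
) -> list[SeedMatchSite]:
    """Find all canonical seed-match sites of ``mirna`` on ``transcript``.

    Every occurrence of the 6-nt seed core's reverse complement defines a
    locus; the locus is reported once with the highest-priority supported
    type that is also in ``site_types`` (or not at all). Sites are sorted
    by start coordinate.
    """
    wanted = set(site_types)
    unknown = wanted - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types {unknown}")
    s7 = reverse_complement(mirna.seed)  # pairs seed 8..2 along 5'->3' target
    s6 = s7[1:]
    m8_base = s7[0]
    seq = transcript.sequence
    sites = []
    i = seq.find(s6)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == m8_base
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        supported = ["6mer"]
        if has_a1:
            supported.append("7mer-A1")
        if has_m8:
            supported.append("7mer-m8")
        if has_m8 and has_a1:
            supported.append("8mer")
        choices = [t for t in supported if t in wanted]
        if choices:
            best = max(choices, key=_PRIORITY.__getitem__)
            if best == "8mer":
                start, end = i - 1, i + 7
            elif best == "7mer-m8":
                start, end = i - 1, i + 6
            elif best == "7mer-A1":
                start, end = i, i + 7
            else:
                start, end = i, i + 6
            sites.append(SeedMatchSite(mirna.name, start, end, best))
        i = seq.find(s6, i + 1)
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def _paired_target(seed: str, site_type: str) -> str:
    """Target-strand 5'->3' string of the Watson-Crick paired region.

    The full 7-nt seed pairs for 8mer and 7mer-m8 sites; only the 6-nt core
    (mature positions 2-7) pairs for 7mer-A1 and 6mer sites. The A opposite
    mature position 1 is recognized unpaired and contributes no stacking.
    """
    s7 = reverse_complement(seed)
    return s7 if site_type in ("8mer", "7mer-m8") else s7[1:]


def duplex_dg(paired: str) -> float:
    """Nearest-neighbor duplex free energy: sum of stacking steps, kcal/mol."""
    return sum(STACKING_DG[paired[i : i + 2]] for i in range(len(paired) - 1))


def ddg_score(
    transcript: NamedSequence, site: SeedMatchSite, mirna: MiRNA
) -> float:
    """ddG of a seed-match site (kcal/mol); more negative = more stable.

    The default energy model returns the seed:target duplex free energy from
    Watson-Crick nearest-neighbor stacking parameters and sets the
    target-opening penalty to zero, so ddG equals dG_duplex. It depends only
    on the duplex (i.e. on the miRNA seed and site type), not on transcript
    context outside the site.
    """
    if not 0 <= site.start < site.end <= len(transcript):
        raise ValueError(f"site {site} does not lie on {transcript.name!r}")
    # the paired region starts at site.start for every type; any trailing A
    # (8mer, 7mer-A1) sits opposite mature position 1 and is unpaired
    paired = _paired_target(mirna.seed, site.site_type)
    observed = transcript.sequence[site.start : site.start + len(paired)]
    if observed != paired:
        raise ValueError(
            f"site/miRNA mismatch: transcript has {observed!r}, "
            f"expected paired region {paired!r} for {mirna.name}"
        )
    return duplex_dg(paired)


def mirna_type_ddg(mirna: MiRNA) -> dict[str, float]:
    """ddG of each site type for this miRNA (constant under the default model)."""
    return {t: duplex_dg(_paired_target(mirna.seed, t)) for t in SITE_TYPES}


def scan_mirna(
    transcript: NamedSequence, mirna: MiRNA, params: ScanParams
) -> list[SeedMatchSite]:
    """Scan for miRNA sites under the configured search mode.

    ``seed_only``
        pure seed matching, no energy annotation.
    ``energy`` / ``intersection``
        seed matches whose duplex ddG passes ``params.ddg_cutoff``
        (intersection of the seed criterion and the energetic criterion).
    ``union``
        all seed matches, ddG annotated.
    """
    sites = scan_seed_sites(transcript, mirna, params.site_types)
    if params.mode == "seed_only":
        return sites
    ddg_by_type = mirna_type_ddg(mirna)
    annotated = [
        SeedMatchSite(s.mirna_name, s.start, s.end, s.site_type,
                      ddg=ddg_by_type[s.site_type])
        for s in sites
    ]
    if params.mode == "union":
        return annotated
    if params.mode in ("energy", "intersection"):
        return [s for s in annotated if s.ddg <= params.ddg_cutoff]
    raise ValueError(f"unknown mode {params.mode!r}")
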