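"""Seeded synthetic antibody repertoires.

Generates paired (heavy+light) and unpaired antibody amino-acid sequences with
the structure the rest of the framework assumes: chains assembled from germline
V and J segments around a randomized, non-templated CDR3 junction, framework
and CDR region annotations in 0-based half-open coordinates, per-chain somatic
mutation counts (zero for naive B cells, positive for memory B cells), native
heavy/light pairing, and optional specificity class labels carrying a learnable
CDR3-motif and germline-usage signal.

The generator makes no claim of biological fidelity at the nucleotide or
allele level; it emulates the gross statistical structure of a B-cell
repertoire (chain lengths, region layout, mutation load, pairing) well enough
to exercise tokenization, curriculum sampling, training, and the downstream
classification tasks.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(CANONICAL_AA)

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

#: CDR3 junction length bounds (inclusive), uniform across chain types.
JUNCTION_LENGTH_RANGE = (5, 20)


@dataclasses.dataclass(frozen=True)
class GermlineLibrary:
    """A small built-in stand-in for germline V/J gene segments.

    All V segments of a chain type share one region layout, so the
    ``region_template`` maps each of FR1, CDR1, FR2, CDR2 and FR3 to its
    interval within the V portion of an assembled chain; CDR3 is the
    randomized junction and FR4 is the J segment.
    """

    heavy_v_segments: tuple[str, ...]
    heavy_j_segments: tuple[str, ...]
    light_v_segments: tuple[str, ...]
    light_j_segments: tuple[str, ...]
    region_template: Mapping[str, Mapping[str, tuple[int, int]]]

    def __post_init__(self):
        for name in ("heavy_v_segments", "heavy_j_segments",
                     "light_v_segments", "light_j_segments"):
            segments = getattr(self, name)
            if not segments:
                raise ConfigurationError(f"germline library has no {name}")
            for seg in segments:
                if not seg or set(seg) - _AA_SET:
                    raise ConfigurationError(
                        f"segment {seg!r} in {name} is not a non-empty string "
                        "over the 20 canonical amino acids")
        for chain in ("heavy", "light"):
            template = self.region_template[chain]
            v_len = len(getattr(self, f"{chain}_v_segments")[0])
            cursor = 0
            for region in REGION_ORDER[:5]:
                start, end = template[region]
                if start != cursor or end <= start:
                    raise ConfigurationError(
                        f"{chain} region template is not contiguous at {region}")
                cursor = end
            if cursor != v_len:
                raise ConfigurationError(
                    f"{chain} region template does not cover the V segment")
            for seg in getattr(self, f"{chain}_v_segments"):
                if len(seg) != v_len:
                    raise ConfigurationError(
                        f"all {chain} V segments must share length {v_len}")


def _template_from_lengths(lengths: Sequence[int]) -> dict[str, tuple[int, int]]:
    out, cursor = {}, 0
    for region, n in zip(REGION_ORDER[:5], lengths):
        out[region] = (cursor, cursor + n)
        cursor += n
    return out


# Hand-written segments loosely styled on human V-gene frameworks; heavy V
# segments are 96 aa (FR1 25, CDR1 8, FR2 17, CDR2 8, FR3 38) and light V
# segments 86 aa (FR1 23, CDR1 7, FR2 15, CDR2 7, FR3 34), so assembled heavy
# chains span ~112-127 aa and light chains ~101-116 aa with a 5-20 aa junction.
_HEAVY_V = (
    "EVQLLESGGGLVQPGGSLRLSCAAS" "GFTFSSYA" "MSWVRQAPGKGLEWVSA" "ISGSGGST"
    "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
    "QVQLVQSGAEVKKPGSSVKVSCKAS" "GGTFSSYA" "ISWVRQAPGQGLEWMGG" "IIPIFGTA"
    "NYAQKFQGRVTITADESTSTAYMELSSLRSEDTAVYYC",
    "QVQLQESGPGLVKPSETLSLTCTVS" "GGSISSYY" "WSWIRQPPGKGLEWIGY" "IYYSGSTN"
    "YYNPSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYC",
    "QVQLVESGGGVVQPGRSLRLSCAAS" "GFTFSSYG" "MHWVRQAPGKGLEWVAV" "IWYDGSNK"
    "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
)
_HEAVY_J = ("WGQGTLVTVSS", "WGQGTTVTVSS")
_LIGHT_V = (
    "DIQMTQSPSSLSASVGDRVTITC" "RASQSIS" "SYLNWYQQKPGKAPK" "LLIYAAS"
    "LQSGVPSRFSGSGSGTDFTLTISSLQPEDFAYYC",
    "EIVLTQSPGTLSLSPGERATLSC" "RASQSVS" "SSYLAWYQQKPGQAP" "RLLIYGA"
    "RATGIPDRFSGSGSGTDFTLTISRLEPEDFAYYC",
    "QSVLTQPPSVSGAPGQRVTISCS" "TGSSSNI" "GAGYDVHWYQQLPGT" "APKLLIY"
    "SNRPSGVPDRFSGSKSGTSASLAITGLQAEDYYC",
    "DIVMTQSPDSLAVSLGERATINC" "KSSQSVL" "YSSNNKNYLAWYQQK" "PGQPPKL"
    "LIYWASTRESGVPDRFSGSGSGTDFTLTISSYYC",
)
_LIGHT_J = ("FGQGTKVEIK", "FGGGTKLTVL")


def default_library() -> GermlineLibrary:
    """The built-in germline library (4 V and 2 J segments per chain type)."""
    return GermlineLibrary(
        heavy_v_segments=_HEAVY_V,
        heavy_j_segments=_HEAVY_J,
        light_v_segments=_LIGHT_V,
        light_j_segments=_LIGHT_J,
        region_template={
            "heavy": _template_from_lengths((25, 8, 17, 8, 38)),
            "light": _template_from_lengths((23, 7, 15, 7, 34)),
        },
    )


@dataclasses.dataclass
class AntibodySequence:
    """One antibody chain with region annotations and mutation load."""

    chain: str  # "heavy" | "light"
    sequence: str
    regions: dict[str, tuple[int, int]]
    mutation_count: int = 0
    germline_id: str = ""
    specificity: Optional[str] = None

    def __post_init__(self):
        if self.chain not in ("heavy", "light"):
            raise ValueError(f"chain must be 'heavy' or 'light', got {self.chain!r}")

    def validate(self) -> None:
        """Assert region tiling, residue alphabet and mutation-count bounds."""
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in sequence")
        if not 0 <= self.mutation_count <= len(self.sequence):
            raise ValueError("mutation_count outside [0, len(sequence)]")
        cursor = 0
        for region in REGION_ORDER:
            if region not in self.regions:
                raise ValueError(f"missing region {region}")
            start, end = self.regions[region]
            if start != cursor:
                raise ValueError(f"region {region} does not tile: gap/overlap at {start}")
            cursor = end
        if cursor != len(self.sequence):
            raise ValueError("regions do not cover the full sequence")


@dataclasses.dataclass
class PairedRecord:
    """A natively paired heavy+light chain pair from a single B cell."""

    heavy: AntibodySequence
    light: AntibodySequence
    pair_id: str
    is_native: bool = True

    def __post_init__(self):
        if self.heavy.chain != "heavy" or self.light.chain != "light":
            raise ValueError("PairedRecord requires a heavy and a light chain")


def _zero_truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    # Poisson(mean) conditioned on >= 1; realized mean is mean / (1 - e^-mean).
    if mean <= 0:
        return 1
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def _assemble_chain(chain: str, library: GermlineLibrary,
                    rng: np.random.Generator) -> AntibodySequence:
    v_segments = getattr(library, f"{chain}_v_segments")
    j_segments = getattr(library, f"{chain}_j_segments")
    vi = int(rng.integers(len(v_segments)))
    ji = int(rng.integers(len(j_segments)))
    v, j = v_segments[vi], j_segments[ji]
    lo, hi = JUNCTION_LENGTH_RANGE
    junction_len = int(rng.integers(lo, hi + 1))
    junction = "".join(CANONICAL_AA[i]
                       for i in rng.integers(20, size=junction_len))
    regions = dict(library.region_template[chain])
    regions["CDR3"] = (len(v), len(v) + junction_len)
    regions["FR4"] = (len(v) + junction_len, len(v) + junction_len + len(j))
    prefix = "IGH" if chain == "heavy" else "IGL"
    return AntibodySequence(
        chain=chain,
        sequence=v + junction + j,
        regions=regions,
        mutation_count=0,
        germline_id=f"{prefix}V{vi + 1}*J{ji + 1}",
    )


def mutate_chain(seq: AntibodySequence, n_mutations: int,
                 rng: np.random.Generator) -> AntibodySequence:
    """Return a copy with exactly ``n_mutations`` substituted positions.

    Positions are drawn without replacement; each substitution picks uniformly
    among the 19 other residues, so the Hamming distance to the input is
    exactly ``n_mutations``. Region annotations are unchanged (substitutions
    only). Emulates somatic hypermutation at the crudest useful level.
    """
    if n_mutations > len(seq.sequence):
        raise ValueError(
            f"n_mutations={n_mutations} exceeds sequence length {len(seq.sequence)}")
    residues = list(seq.sequence)
    positions = rng.choice(len(residues), size=n_mutations, replace=False)
    for pos in positions:
        alternatives = CANONICAL_AA.replace(residues[pos], "")
        residues[pos] = alternatives[int(rng.integers(19))]
    return dataclasses.replace(
        seq, sequence="".join(residues),
        regions=dict(seq.regions),
        mutation_count=seq.mutation_count + int(n_mutations))


def _maybe_mutate(seq: AntibodySequence, is_naive: bool, mutation_rate: float,
                  rng: np.random.Generator) -> AntibodySequence:
    if is_naive:
        return seq
    n = min(_zero_truncated_poisson(rng, mutation_rate), len(seq.sequence))
    return mutate_chain(seq, n, rng)


def generate_repertoire(
    n_paired: int,
    n_unpaired_heavy: int,
    n_unpaired_light: int,
    mutation_rate: float = 6.0,
    naive_fraction: float = 0.5,
    seed: int = 0,
    library: Optional[GermlineLibrary] = None,
) -> tuple[list[PairedRecord], list[AntibodySequence]]:
    """Generate a seeded synthetic repertoire of paired and unpaired chains.

    Parameters
    ----------
    n_paired, n_unpaired_heavy, n_unpaired_light
        Exact output counts.
    mutation_rate
        Mean somatic mutations per memory-cell chain (zero-truncated Poisson).
    naive_fraction
        Probability that a record is a naive B cell (mutation_count 0 on all
        of its chains); memory records carry >= 1 mutation per chain.
    seed
        Seeds all randomness; identical arguments give byte-identical output.
    """
    if min(n_paired, n_unpaired_heavy, n_unpaired_light) < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= naive_fraction <= 1.0:
        raise ValueError("naive_fraction must lie in [0, 1]")
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be non-negative")
    library = library or default_library()
    rng = np.random.default_rng(seed)

    pairs: list[PairedRecord] = []
    for i in range(n_paired):
        naive = rng.random() < naive_fraction
        heavy = _maybe_mutate(_assemble_chain("heavy", library, rng),
                              naive, mutation_rate, rng)
        light = _maybe_mutate(_assemble_chain("light", library, rng),
                              naive, mutation_rate, rng)
        pairs.append(PairedRecord(heavy=heavy, light=light, pair_id=f"P{i:06d}"))

    unpaired: list[AntibodySequence] = []
    for chain, count in (("heavy", n_unpaired_heavy), ("light", n_unpaired_light)):
        for _ in range(count):
            naive = rng.random() < naive_fraction
            unpaired.append(_maybe_mutate(_assemble_chain(chain, library, rng),
                                          naive, mutation_rate, rng))
    return pairs, unpaired


#: class -> (CDR3 motif planted at the junction start, preferred heavy V index)
SPECIFICITY_SIGNATURES: dict[str, tuple[Optional[str], Optional[int]]] = {
    "HD": (None, None),
    "Flu": ("RGY", 1),
    "CoV": ("DWS", 3),
}


def generate_specificity_pools(
    n_per_class: int,
    classes: Sequence[str] = ("HD", "Flu", "CoV"),
    motif_strength: float = 0.8,
    mutation_rate: float = 6.0,
    naive_fraction: float = 0.2,
    seed: int = 0,
    library: Optional[GermlineLibrary] = None,
) -> dict[str, list[PairedRecord]]:
    """Paired records with a learnable per-class signal.

    Antigen-specific classes carry a class-specific 3-mer planted at the start
    of the heavy CDR3 with probability ``motif_strength``, plus a biased heavy
    V-gene choice; healthy-donor (HD) sequences are unbiased. The signal is
    synthetic by construction — it exists so specificity classifiers have
    something learnable, not to mimic real epitope-driven convergence.
    """
    if not 0.0 <= motif_strength <= 1.0:
        raise ValueError("motif_strength must lie in [0, 1]")
    library = library or default_library()
    pools: dict[str, list[PairedRecord]] = {}
    for ci, cls in enumerate(classes):
        motif, v_bias = SPECIFICITY_SIGNATURES.get(cls, (None, None))
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        records: list[PairedRecord] = []
        for i in range(n_per_class):
            naive = rng.random() < naive_fraction
            heavy = _assemble_chain("heavy", library, rng)
            light = _assemble_chain("light", library, rng)
            if v_bias is not None and rng.random() < motif_strength:
                forced = _assemble_chain("heavy", library, rng)
                while forced.germline_id != f"IGHV{v_bias + 1}*J1" and \
                        not forced.germline_id.startswith(f"IGHV{v_bias + 1}*"):
                    forced = _assemble_chain("heavy", library, rng)
                heavy = forced
            if motif is not None and rng.random() < motif_strength:
                start, end = heavy.regions["CDR3"]
                s = heavy.sequence
                heavy = dataclasses.replace(
                    heavy,
                    sequence=s[:start] + motif + s[start + len(motif):],
                    regions=dict(heavy.regions))
            heavy = _maybe_mutate(heavy, naive, mutation_rate, rng)
            light = _maybe_mutate(light, naive, mutation_rate, rng)
            heavy.specificity = light.specificity = cls
            records.append(PairedRecord(heavy=heavy, light=light,
                                        pair_id=f"{cls}{i:06d}"))
        pools[cls] = records
    return pools


# ---------------------------------------------------------------------------
# Writers

def _regions_str(regions: Mapping[str, tuple[int, int]]) -> str:
    return ";".join(f"{r}:{a}-{b}" for r, (a, b) in regions.items())


def parse_regions(text: str) -> dict[str, tuple[int, int]]:
    out = {}
    for part in text.split(";"):
        name, span = part.split(":")
        a, b = span.split("-")
        out[name] = (int(a), int(b))
    return out


def write_fasta(path: str | Path, pairs: Iterable[PairedRecord],
                unpaired: Iterable[AntibodySequence] = ()) -> None:
    """One record per chain; pair mates share an id with /H and /L suffixes."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for pair in pairs:
        for suffix, chain in (("H", pair.heavy), ("L", pair.light)):
            records.append(SeqRecord(
                Seq(chain.sequence), id=f"{pair.pair_id}/{suffix}",
                description=f"mutations={chain.mutation_count}"))
    for i, chain in enumerate(unpaired):
        tag = "H" if chain.chain == "heavy" else "L"
        records.append(SeqRecord(
            Seq(chain.sequence), id=f"U{i:06d}/{tag}",
            description=f"mutations={chain.mutation_count}"))
    seqio_write(records, str(path), "fasta")


CSV_COLUMNS = ("pair_id", "chain", "sequence", "regions", "mutation_count",
               "germline_id", "specificity")


def write_csv(path: str | Path, pairs: Iterable[PairedRecord],
              unpaired: Iterable[AntibodySequence] = ()) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)

        def row(pair_id, chain: AntibodySequence):
            writer.writerow([pair_id, chain.chain, chain.sequence,
                             _regions_str(chain.regions), chain.mutation_count,
                             chain.germline_id, chain.specificity or ""])

        for pair in pairs:
            row(pair.pair_id, pair.heavy)
            row(pair.pair_id, pair.light)
        for i, chain in enumerate(unpaired):
            row(f"U{i:06d}", chain)


def read_csv(path: str | Path) -> tuple[list[PairedRecord], list[AntibodySequence]]:
    """Read the CSV dialect written by :func:`write_csv`."""
    by_id: dict[str, dict[str, AntibodySequence]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            seq = AntibodySequence(
                chain=rec["chain"], sequence=rec["sequence"],
                regions=parse_regions(rec["regions"]),
                mutation_count=int(rec["mutation_count"]),
                germline_id=rec["germline_id"],
                specificity=rec["specificity"] or None)
            if rec["pair_id"] not in by_id:
                order.append(rec["pair_id"])
            by_id.setdefault(rec["pair_id"], {})[seq.chain] = seq
    pairs, unpaired = [], []
    for pid in order:
        chains = by_id[pid]
        if "heavy" in chains and "light" in chains:
            pairs.append(PairedRecord(heavy=chains["heavy"],
                                      light=chains["light"], pair_id=pid))
        else:
            unpaired.extend(chains.values())
    return pairs, unpaired
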