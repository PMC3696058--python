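"""Alignment and population-metadata I/O.

Reads aligned mtDNA FASTA files and tabular population maps, applies the
filtering rules the downstream statistics assume (complete deletion of
gap/N columns, exclusion of under-sampled localities), collapses identical
sequences into haplotypes, and concatenates loci sequenced on the same
individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")
#: IUPAC ambiguity codes other than N (mapped to N or rejected per config)
AMBIGUITY_CODES = set("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


class JoinError(KeyError):
    """Raised when individuals cannot be matched between structures."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length DNA alignment with per-individual identifiers.

    ``records`` is an ordered tuple of ``(individual_id, sequence)`` pairs;
    sequences are upper-case strings over ``{A, C, G, T, N, -}``.
    """

    records: tuple[tuple[str, str], ...]
    length: int
    locus_label: str = ""

    def __post_init__(self):
        if self.length <= 0:
            raise AlignmentError("alignment length must be positive")
        seen = set()
        for ind, seq in self.records:
            if len(seq) != self.length:
                raise AlignmentError(
                    f"record {ind!r} has length {len(seq)}, expected {self.length}"
                )
            if ind in seen:
                raise AlignmentError(f"duplicate individual id {ind!r}")
            seen.add(ind)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind for ind, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def sequence_of(self, individual_id: str) -> str:
        for ind, seq in self.records:
            if ind == individual_id:
                return seq
        raise JoinError(individual_id)

    def subset(self, keep_ids: Iterable[str]) -> "AlignedSequenceSet":
        keep = set(keep_ids)
        recs = tuple((i, s) for i, s in self.records if i in keep)
        if not recs:
            raise AlignmentError("subset removed every record")
        return AlignedSequenceSet(recs, self.length, self.locus_label)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], locus_label: str = ""
    ) -> "AlignedSequenceSet":
        recs = tuple((i, s.upper()) for i, s in pairs)
        if not recs:
            raise AlignmentError("empty record set")
        return cls(recs, len(recs[0][1]), locus_label)


@dataclass(frozen=True)
class PopulationMap:
    """individual_id -> (locality, optional group, optional coordinates)."""

    entries: Mapping[str, dict]

    def __post_init__(self):
        for ind, meta in self.entries.items():
            if not meta.get("locality"):
                raise ValueError(f"individual {ind!r} has an empty locality code")

    def locality_of(self, individual_id: str) -> str:
        try:
            return self.entries[individual_id]["locality"]
        except KeyError:
            raise JoinError(f"individual {individual_id!r} absent from population map")

    def localities(self) -> list[str]:
        """Distinct locality codes in first-appearance order."""
        out: list[str] = []
        for meta in self.entries.values():
            loc = meta["locality"]
            if loc not in out:
                out.append(loc)
        return out

    def individuals_by_locality(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, meta in self.entries.items():
            out.setdefault(meta["locality"], []).append(ind)
        return out

    def subset(self, keep_ids: Iterable[str]) -> "PopulationMap":
        keep = set(keep_ids)
        return PopulationMap({i: m for i, m in self.entries.items() if i in keep})


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique sequences with per-locality counts.

    Haplotypes are ordered by decreasing total count, ties broken by first
    occurrence in the source alignment, and labelled H1, H2, ...
    """

    haplotypes: tuple[dict, ...]  # haplotype_id, sequence, total_count, counts_by_locality

    def __post_init__(self):
        seqs = [h["sequence"] for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences must be pairwise distinct")
        for h in self.haplotypes:
            if h["total_count"] != sum(h["counts_by_locality"].values()):
                raise ValueError(
                    f"haplotype {h['haplotype_id']}: total != sum of locality counts"
                )

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_individuals(self) -> int:
        return sum(h["total_count"] for h in self.haplotypes)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(h["total_count"] for h in self.haplotypes)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(h["sequence"] for h in self.haplotypes)

    def to_frame(self) -> pd.DataFrame:
        locs: list[str] = []
        for h in self.haplotypes:
            for loc in h["counts_by_locality"]:
                if loc not in locs:
                    locs.append(loc)
        rows = []
        for h in self.haplotypes:
            row = {
                "haplotype_id": h["haplotype_id"],
                "sequence": h["sequence"],
                "total": h["total_count"],
            }
            for loc in locs:
                row[loc] = h["counts_by_locality"].get(loc, 0)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    path: str | Path,
    locus_label: str = "",
    ambiguity: str = "reject",
) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Characters are upper-cased and U is mapped to T. IUPAC ambiguity codes
    other than N are rejected (``ambiguity="reject"``, default) or mapped to
    N (``ambiguity="to_n"``). Description text after the first whitespace is
    ignored for identity.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    pairs = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - VALID_CHARS
        if bad & AMBIGUITY_CODES:
            if ambiguity == "to_n":
                seq = "".join("N" if c in AMBIGUITY_CODES else c for c in seq)
                bad = set(seq) - VALID_CHARS
            else:
                raise AlignmentError(
                    f"record {rec.id!r} contains ambiguity codes {sorted(bad & AMBIGUITY_CODES)}"
                )
        if bad:
            raise AlignmentError(f"record {rec.id!r} contains invalid characters {sorted(bad)}")
        pairs.append((rec.id, seq))
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        off = next(i for i, s in pairs if len(s) != len(pairs[0][1]))
        raise AlignmentError(
            f"unequal sequence lengths {sorted(lengths)}; first offending record {off!r}"
        )
    return AlignedSequenceSet(tuple(pairs), lengths.pop(), locus_label or path.stem)


def write_fasta_alignment(aln: AlignedSequenceSet, path: str | Path) -> Path:
    path = Path(path)
    recs = [
        SeqRecord(Seq(seq), id=ind, description="") for ind, seq in aln.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)
    return path


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a delimited population map with header ``individual,locality[,group,lat,lon]``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "individual" not in cols or "locality" not in cols:
        raise ValueError("population map must have 'individual' and 'locality' columns")
    if df[cols["individual"]].duplicated().any():
        dup = df[cols["individual"]][df[cols["individual"]].duplicated()].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r} in population map")
    entries = {}
    for _, row in df.iterrows():
        meta = {"locality": row[cols["locality"]]}
        if "group" in cols and pd.notna(row[cols["group"]]):
            meta["group"] = row[cols["group"]]
        for key in ("lat", "lon"):
            if key in cols and pd.notna(row[cols[key]]):
                meta[key] = float(row[cols[key]])
        # unknown columns preserved as opaque metadata
        for c in df.columns:
            if c.lower() not in {"individual", "locality", "group", "lat", "lon"}:
                meta.setdefault("extra", {})[c] = row[c]
        entries[row[cols["individual"]]] = meta
    return PopulationMap(entries)


def write_population_map(pm: PopulationMap, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for ind, meta in pm.entries.items():
        rows.append(
            {
                "individual": ind,
                "locality": meta["locality"],
                "group": meta.get("group", ""),
                "lat": meta.get("lat", ""),
                "lon": meta.get("lon", ""),
            }
        )
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def drop_gap_sites(
    aln: AlignedSequenceSet, mode: str = "complete"
) -> tuple[AlignedSequenceSet, list[int]]:
    """Remove alignment columns containing '-' or 'N'.

    ``mode="complete"`` (default) drops the whole column if any retained
    sequence carries a gap or N there, so every statistic downstream sees a
    single consistent site set. Returns the filtered alignment and the list
    of retained 0-based site indices.
    """
    if mode not in {"complete", "none"}:
        raise ValueError(f"unknown gap mode {mode!r}")
    if mode == "none":
        return aln, list(range(aln.length))
    keep = [
        j
        for j in range(aln.length)
        if all(seq[j] not in "-N" for seq in aln.sequences)
    ]
    if not keep:
        raise AlignmentError("every column contains a gap or N; nothing retained")
    if len(keep) == aln.length:
        return aln, keep
    recs = tuple(
        (ind, "".join(seq[j] for j in keep)) for ind, seq in aln.records
    )
    return AlignedSequenceSet(recs, len(keep), aln.locus_label), keep


def concatenate_loci(
    a: AlignedSequenceSet, b: AlignedSequenceSet
) -> tuple[AlignedSequenceSet, list[str]]:
    """Inner-join two loci on individual id and concatenate the sequences.

    Individuals present in only one locus are dropped and returned in the
    second element, in the order they appear in either input.
    """
    ids_a, ids_b = set(a.ids), set(b.ids)
    shared = [i for i in a.ids if i in ids_b]
    if not shared:
        raise JoinError("no individuals shared between the two loci")
    dropped = [i for i in a.ids if i not in ids_b] + [i for i in b.ids if i not in ids_a]
    seq_b = dict(b.records)
    recs = tuple((i, a.sequence_of(i) + seq_b[i]) for i in shared)
    label = f"{a.locus_label}+{b.locus_label}".strip("+")
    return AlignedSequenceSet(recs, a.length + b.length, label), dropped


def collapse_haplotypes(aln: AlignedSequenceSet, pm: PopulationMap) -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-locality counts.

    Haplotype identity is exact string equality (run :func:`drop_gap_sites`
    first under the default policy). Ordering: decreasing total count, ties
    by first occurrence.
    """
    order: list[str] = []
    total: dict[str, int] = {}
    by_loc: dict[str, dict[str, int]] = {}
    for ind, seq in aln.records:
        loc = pm.locality_of(ind)
        if seq not in total:
            order.append(seq)
            total[seq] = 0
            by_loc[seq] = {}
        total[seq] += 1
        by_loc[seq][loc] = by_loc[seq].get(loc, 0) + 1
    ranked = sorted(order, key=lambda s: (-total[s], order.index(s)))
    haps = tuple(
        {
            "haplotype_id": f"H{k + 1}",
            "sequence": s,
            "total_count": total[s],
            "counts_by_locality": dict(by_loc[s]),
        }
        for k, s in enumerate(ranked)
    )
    return HaplotypeTable(haps)


def filter_min_sample_size(
    pm: PopulationMap,
    aln: AlignedSequenceSet,
    min_n: int = 5,
) -> tuple[PopulationMap, AlignedSequenceSet, dict[str, int]]:
    """Drop localities sampled below ``min_n`` individuals.

    Mirrors the exclusion of under-sampled localities from population-level
    statistics (default threshold 5). Returns the filtered map and
    alignment plus a report ``{removed_locality: n}``.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts: dict[str, int] = {}
    for ind in aln.ids:
        loc = pm.locality_of(ind)
        counts[loc] = counts.get(loc, 0) + 1
    removed = {loc: n for loc, n in counts.items() if n < min_n}
    if not removed:
        return pm, aln, {}
    keep_ids = [i for i in aln.ids if pm.locality_of(i) not in removed]
    if len(set(counts) - set(removed)) < 2:
        raise AlignmentError(
            "fewer than 2 localities remain after the minimum-sample filter; "
            "population-level statistics are infeasible"
        )
    return pm.subset(keep_ids), aln.subset(keep_ids), removed


def join_check(aln: AlignedSequenceSet, pm: PopulationMap) -> None:
    """Every aligned individual must be mapped; unmapped map rows only warn."""
    missing = [i for i in aln.ids if i not in pm.entries]
    if missing:
        raise JoinError(f"individuals missing from population map: {missing[:5]}")
    extra = [i for i in pm.entries if i not in set(aln.ids)]
    if extra:
        warnings.warn(
            f"{len(extra)} individuals in the population map have no sequence",
            stacklevel=2,
        )
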