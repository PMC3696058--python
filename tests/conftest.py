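import numpy as np
import pytest

from mtpopgen import AlignedSequenceSet, HaplotypeTable, PopulationMap


@pytest.fixture
def make_aln():
    """Build an AlignedSequenceSet from raw sequences (auto ids)."""

    def _make(seqs, ids=None, locus="test"):
        ids = ids or [f"ind{i+1}" for i in range(len(seqs))]
        return AlignedSequenceSet.from_pairs(zip(ids, seqs), locus_label=locus)

    return _make


@pytest.fixture
def make_pm():
    """Build a PopulationMap from {individual: locality}."""

    def _make(mapping):
        return PopulationMap({i: {"locality": loc} for i, loc in mapping.items()})

    return _make


@pytest.fixture
def make_ht():
    """Build a HaplotypeTable from sequences (+ optional counts/localities)."""

    def _make(seqs, counts=None, locality="L1"):
        counts = counts or [1] * len(seqs)
        return HaplotypeTable(
            tuple(
                {
                    "haplotype_id": f"H{i+1}",
                    "sequence": s,
                    "total_count": c,
                    "counts_by_locality": {locality: c},
                }
                for i, (s, c) in enumerate(zip(seqs, counts))
            )
        )

    return _make


@pytest.fixture
def random_alignment(make_aln):
    """Seeded random alignment factory (n sequences of length L, with a
    configurable per-site substitution probability off a random ancestor)."""

    def _make(n, L, p=0.05, seed=0, alphabet="ACGT"):
        rng = np.random.default_rng(seed)
        root = rng.choice(list(alphabet), L)
        seqs = []
        for _ in range(n):
            s = root.copy()
            mask = rng.random(L) < p
            for j in np.nonzero(mask)[0]:
                s[j] = rng.choice([b for b in alphabet if b != s[j]])
            seqs.append("".join(s))
        return _make_unique_ids(seqs, make_aln)

    def _make_unique_ids(seqs, make_aln):
        return make_aln(seqs)

    return _make
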