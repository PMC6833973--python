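import textwrap

import numpy as np
import pytest

from vsdflex.msa_consensus import AMINO_ACIDS, Alignment, ColumnProfile


THREE_SEQS = {
    "seq1": "MNAADVKLFWGT",
    "seq2": "MNASDVKLFWGT",
    "seq3": "MNAADVRLFWGT",
}


@pytest.fixture
def fasta_alignment(tmp_path):
    path = tmp_path / "fam1.fasta"
    path.write_text(
        "".join(f">{name}\n{seq}\n" for name, seq in THREE_SEQS.items())
    )
    return path


@pytest.fixture
def clustal_alignment(tmp_path):
    body = "\n".join(f"{name:<10}{seq}" for name, seq in THREE_SEQS.items())
    path = tmp_path / "fam1.aln"
    path.write_text(f"CLUSTAL W (2.0) multiple sequence alignment\n\n{body}\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n_seqs=8, length=30, family_id="rand"):
    records = tuple(
        (
            f"s{i}",
            "".join(rng.choice(list(AMINO_ACIDS), size=length)),
        )
        for i in range(n_seqs)
    )
    return Alignment(family_id=family_id, records=records)


def profile_from_counts(position, counts):
    total = sum(counts.values())
    return ColumnProfile(
        position=position,
        counts=dict(counts),
        frequencies={r: c / total for r, c in counts.items()},
        gap_fraction=0.0,
    )
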