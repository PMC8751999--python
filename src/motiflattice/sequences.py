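"""Motif sequences over the two-letter alphabet {A, B}.

A motif is a monomer that can form exactly one specific bond with a
monomer of the complementary type (A with B).  Sequences are immutable
strings plus bookkeeping: length ``L``, the number of A motifs ``a`` and
B motifs ``b``, and a free-text label (for block sequences the label
records the block size ``ell``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

A, B = 0, 1  # integer motif codes used by the simulation engine


@dataclass(frozen=True)
class MotifSequence:
    """An ordered A/B motif string with stoichiometry metadata."""

    motifs: str
    label: str = ""

    def __post_init__(self):
        if len(self.motifs) < 1:
            raise ValueError("sequence must contain at least one motif")
        bad = set(self.motifs) - {"A", "B"}
        if bad:
            raise ValueError(f"sequence may only contain A and B, got {bad}")

    @property
    def L(self) -> int:
        return len(self.motifs)

    @property
    def a(self) -> int:
        return self.motifs.count("A")

    @property
    def b(self) -> int:
        return self.motifs.count("B")

    def codes(self) -> np.ndarray:
        """Motif types as a uint8 array (0 = A, 1 = B)."""
        return np.frombuffer(
            self.motifs.encode().translate(bytes.maketrans(b"AB", b"\x00\x01")),
            dtype=np.uint8,
        ).copy()

    def __str__(self):
        return self.motifs


def make_block_sequence(L: int, block: int) -> MotifSequence:
    """Alternating runs of ``block`` A's then ``block`` B's, starting with A.

    ``L`` must be divisible by ``2*block`` so that a = b = L/2.
    """
    if L < 2 or L % 2:
        raise ValueError(f"L must be a positive even number, got {L}")
    if block < 1 or L % (2 * block):
        raise ValueError(
            f"L={L} is not divisible by 2*block={2 * block}; block sequences "
            "need an integer number of AB block pairs"
        )
    motifs = ("A" * block + "B" * block) * (L // (2 * block))
    return MotifSequence(motifs, label=f"block ell={block} L={L}")


def make_scrambled_sequence(L: int, a: int, seed: int) -> MotifSequence:
    """A uniformly random permutation of ``a`` A's and ``L - a`` B's."""
    if not 0 <= a <= L:
        raise ValueError(f"need 0 <= a <= L, got a={a}, L={L}")
    rng = np.random.default_rng(seed)
    letters = np.array(list("A" * a + "B" * (L - a)))
    rng.shuffle(letters)
    return MotifSequence("".join(letters), label=f"scrambled a={a} L={L} seed={seed}")


def mutate_sequence(base: MotifSequence, flips: int, seed: int) -> MotifSequence:
    """Mutate ``flips`` uniformly chosen B motifs of ``base`` into A motifs."""
    if flips > base.b:
        raise ValueError(
            f"cannot flip {flips} B motifs, sequence has only b={base.b}"
        )
    rng = np.random.default_rng(seed)
    b_positions = [i for i, m in enumerate(base.motifs) if m == "B"]
    chosen = rng.choice(len(b_positions), size=flips, replace=False)
    motifs = list(base.motifs)
    for idx in chosen:
        motifs[b_positions[idx]] = "A"
    return MotifSequence(
        "".join(motifs), label=f"{base.label or base.motifs}+{flips} B->A flips"
    )


def fig_block_family(L: int = 24):
    """The family of equal-stoichiometry block sequences of length ``L``."""
    return [
        make_block_sequence(L, ell)
        for ell in range(1, L // 2 + 1)
        if L % (2 * ell) == 0
    ]


# -- sequence file dialect -------------------------------------------------
# Plain text, one A/B string per line, '#' comments.  FASTA is also
# accepted, with headers used as labels.

def read_sequences(path) -> list[MotifSequence]:
    seqs: list[MotifSequence] = []
    label = ""
    fasta_chunks: list[str] = []

    def flush():
        nonlocal fasta_chunks, label
        if fasta_chunks:
            seqs.append(MotifSequence("".join(fasta_chunks), label=label))
            fasta_chunks = []
            label = ""

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                label = line[1:].strip()
            elif fasta_chunks or label:
                fasta_chunks.append(line)
            else:
                seqs.append(MotifSequence(line))
    flush()
    return seqs


def write_sequences(path, seqs) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            if s.label:
                fh.write(f"# {s.label}\n")
            fh.write(s.motifs + "\n")
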