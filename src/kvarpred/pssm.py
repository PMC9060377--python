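"""PSI-BLAST ASCII PSSM parsing and substitution-score features.

The evolutionary feature of a substitution is the log-odds score of the mutant
residue minus that of the wild-type residue at the same position, read from a
position-specific scoring matrix produced by iterative homology search (one
matrix per sequence database, e.g. NR and UniRef50).  Identity substitutions
score exactly zero, which is what lets a conservation-only model recognize
non-perturbing variants.

Only the first 20 columns of the ASCII matrix (the log-odds block) are used;
the weighted-percentage block is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .aatables import CANONICAL_AAS
from .datasets import VariantSpec

#: Residue column order of the PSI-BLAST ASCII log-odds block.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


class PssmError(ValueError):
    """Malformed PSSM file or inconsistent lookup."""


@dataclass
class PssmMatrix:
    """Per-position log-odds substitution scores; positions are 1-based."""

    wt_sequence: str               # length L, one-letter codes
    scores: np.ndarray             # (L, 20) int, columns in PSSM_ALPHABET order
    source: str = ""               # database tag, e.g. "NR" or "UniRef50"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.wt_sequence), 20):
            raise PssmError(
                f"score block shape {self.scores.shape} does not match "
                f"sequence length {len(self.wt_sequence)}"
            )

    def __len__(self) -> int:
        return len(self.wt_sequence)

    def score(self, position: int, aa: str) -> int:
        if not 1 <= position <= len(self):
            raise PssmError(f"position {position} out of range 1..{len(self)}")
        try:
            col = PSSM_ALPHABET.index(aa)
        except ValueError:
            raise PssmError(f"unknown residue code {aa!r}") from None
        return int(self.scores[position - 1, col])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PssmMatrix)
            and self.wt_sequence == other.wt_sequence
            and np.array_equal(self.scores, other.scores)
        )


def parse_pssm(path: str | Path, source: str = "") -> PssmMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Rows look like ``  12 L   -2  1 ... (20 log-odds) [20 percentages ...]``.
    The header is located by the residue-letter column line; parse errors
    report the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in CANONICAL_AAS for t in toks[:20]):
            header_idx = i
            break
    if header_idx is None:
        raise PssmError(f"{path.name}: no PSSM column header found")
    header = lines[header_idx].split()[:20]
    if "".join(header) != PSSM_ALPHABET:
        raise PssmError(
            f"{path.name} line {header_idx + 1}: unexpected residue column order"
        )
    seq: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        toks = line.split()
        if not toks:
            break  # blank line terminates the matrix block
        if not toks[0].isdigit():
            break  # footer (K/Lambda lines etc.)
        if int(toks[0]) != expected_pos:
            raise PssmError(f"{path.name} line {lineno}: positions not contiguous")
        if len(toks) < 22:
            raise PssmError(f"{path.name} line {lineno}: truncated row")
        aa = toks[1]
        if aa not in CANONICAL_AAS:
            raise PssmError(f"{path.name} line {lineno}: bad residue {aa!r}")
        try:
            row = [int(t) for t in toks[2:22]]
        except ValueError:
            raise PssmError(f"{path.name} line {lineno}: non-integer score") from None
        seq.append(aa)
        rows.append(row)
        expected_pos += 1
    if not rows:
        raise PssmError(f"{path.name}: header present but no score rows")
    return PssmMatrix("".join(seq), np.array(rows, dtype=int), source=source)


def write_pssm(matrix: PssmMatrix, path: str | Path) -> None:
    """Write a matrix back out in the ASCII dialect ``parse_pssm`` reads."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(PSSM_ALPHABET) + "   "
                 + "   ".join(PSSM_ALPHABET) + "\n")
        for i, aa in enumerate(matrix.wt_sequence):
            scores = "  ".join(f"{s:4d}" for s in matrix.scores[i])
            pct = "  ".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {aa} {scores}  {pct}  0.00 0.00\n")
        fh.write("\n")


def delta_pssm(pssm: PssmMatrix, variant: VariantSpec) -> int:
    """Log-odds score of the mutant minus the wild type at the variant position."""
    wt_in_matrix = pssm.wt_sequence[variant.position - 1] if variant.position <= len(pssm) else None
    if wt_in_matrix is None:
        raise PssmError(f"position {variant.position} out of range 1..{len(pssm)}")
    if wt_in_matrix != variant.wt_aa:
        raise PssmError(
            f"wild-type mismatch at position {variant.position}: matrix has "
            f"{wt_in_matrix}, variant claims {variant.wt_aa}"
        )
    return pssm.score(variant.position, variant.mut_aa) - pssm.score(
        variant.position, variant.wt_aa
    )
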