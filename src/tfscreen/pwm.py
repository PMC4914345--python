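"""Position weight matrices: TRANSFAC flat-file I/O, MSS scoring, promoter scanning.

A :class:`PWMatrix` holds per-position base counts for a transcription-factor
binding motif.  Sites are scored with the matrix similarity score (MSS): the
information-weighted sum of position frequencies, min--max normalised to
[0, 1] so that 1.0 is reached exactly by the consensus sequence and 0.0 by
the anti-consensus.  Scanning evaluates every window of a promoter on both
strands against a score threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifParseError(ValueError):
    """Raised when a TRANSFAC flat file cannot be parsed."""


class DegenerateMatrixError(ValueError):
    """Raised when a matrix carries no information at any position."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMatrix:
    """A position base-count matrix with derived MSS scoring parameters.

    Parameters
    ----------
    motif_id : str
        Identifier of the motif (TRANSFAC ``ID`` field).
    counts : (L, 4) array
        Non-negative base counts per position, columns ordered A, C, G, T.
    pseudocount : float
        Added to every cell before frequencies are formed, default 0.25 per
        base, so no frequency is ever zero.
    name : str
        Optional descriptive name (TRANSFAC ``NA`` field).
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.25
    name: str = ""
    # derived, filled in __post_init__
    freqs: np.ndarray = field(init=False, repr=False)
    info: np.ndarray = field(init=False, repr=False)
    _weights: np.ndarray = field(init=False, repr=False)
    smin: float = field(init=False)
    smax: float = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: counts must be (L, 4), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        self.counts = counts
        if len(self) < 4:
            warnings.warn(f"motif {self.motif_id}: length {len(self)} < 4", stacklevel=2)
        padded = counts + self.pseudocount
        self.freqs = padded / padded.sum(axis=1, keepdims=True)
        # information weight per position: sum_b f ln(4 f); 0 for a uniform
        # position, ln(4) for a fully determined one
        self.info = (self.freqs * np.log(4.0 * self.freqs)).sum(axis=1)
        self._weights = self.info[:, None] * self.freqs
        self.smin = float(self._weights.min(axis=1).sum())
        self.smax = float(self._weights.max(axis=1).sum())
        if not self.smax > self.smin:
            raise DegenerateMatrixError(
                f"motif {self.motif_id}: uninformative matrix (smin == smax)"
            )

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def score_site(self, subsequence: str) -> float:
        """MSS of one window; ``N`` contributes the position minimum.

        The raw score ``S = sum_i I(i) * f_i(b_i)`` is normalised as
        ``(S - Smin) / (Smax - Smin)`` so the consensus scores 1.0.
        """
        sub = subsequence.upper()
        if len(sub) != len(self):
            raise ValueError(
                f"subsequence length {len(sub)} != motif length {len(self)}"
            )
        s = 0.0
        for i, b in enumerate(sub):
            if b == "N":
                s += self._weights[i].min()
            else:
                try:
                    s += self._weights[i, _BASE_INDEX[b]]
                except KeyError:
                    raise ValueError(f"invalid base {b!r} in subsequence") from None
        return (s - self.smin) / (self.smax - self.smin)

    def reverse_complement(self) -> "PWMatrix":
        """Matrix scoring the reverse complement of this motif's sites."""
        return PWMatrix(
            motif_id=self.motif_id,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            name=self.name,
        )

    def _score_windows(self, encoded: np.ndarray) -> np.ndarray:
        """Normalised scores of every window of an integer-encoded sequence.

        ``encoded`` uses 0..3 for A,C,G,T and 4 for N.
        """
        L = len(self)
        n_win = encoded.size - L + 1
        if n_win <= 0:
            return np.empty(0)
        # 5th column handles N as the per-position minimum weight
        w = np.hstack([self._weights, self._weights.min(axis=1, keepdims=True)])
        windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
        raw = w[np.arange(L), windows].sum(axis=1)
        return (raw - self.smin) / (self.smax - self.smin)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to integers 0..4."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES + "N"):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    out = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return out.astype(np.intp)


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based, leftmost base of the window on the forward strand
    strand: str  # '+' or '-'
    score: float


def scan_promoter(
    pwm: PWMatrix,
    sequence: str,
    threshold: float = 0.85,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All windows scoring >= threshold, ordered by (position, strand).

    Positions are 1-based on the forward strand and refer to the leftmost
    base of the matched window regardless of strand.  A sequence shorter
    than the motif yields an empty hit list.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if len(sequence) < len(pwm):
        return []
    enc = encode_sequence(sequence)
    hits: list[MotifHit] = []
    scores_fwd = pwm._score_windows(enc)
    for pos in np.flatnonzero(scores_fwd >= threshold):
        hits.append(MotifHit(int(pos) + 1, "+", float(scores_fwd[pos])))
    if both_strands:
        # scoring the forward sequence with the reverse-complement matrix is
        # equivalent to scoring each window's reverse complement
        scores_rev = pwm.reverse_complement()._score_windows(enc)
        for pos in np.flatnonzero(scores_rev >= threshold):
            hits.append(MotifHit(int(pos) + 1, "-", float(scores_rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def has_hit(
    pwm: PWMatrix, sequence: str, threshold: float = 0.85, both_strands: bool = True
) -> bool:
    """Whether a promoter contains at least one site at the threshold."""
    if len(sequence) < len(pwm):
        return False
    enc = encode_sequence(sequence)
    if bool((pwm._score_windows(enc) >= threshold).any()):
        return True
    if both_strands:
        return bool((pwm.reverse_complement()._score_windows(enc) >= threshold).any())
    return False


# ---------------------------------------------------------------------------
# TRANSFAC flat-file I/O
# ---------------------------------------------------------------------------

def parse_transfac(path) -> list[PWMatrix]:
    """Parse a TRANSFAC flat file into a list of matrices, order preserved.

    Records are terminated by ``//``; an ``ID`` line names the motif, an
    optional ``NA`` line gives a description, and numbered rows carry four
    base counts (A C G T) with an optional consensus letter.  ``P0``/``PO``
    header lines and ``XX`` separators are skipped.  Malformed content
    raises :class:`MotifParseError` naming the record and line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    matrices: list[PWMatrix] = []
    motif_id: str | None = None
    name = ""
    rows: list[list[float]] = []
    open_record = False

    def flush(lineno: int) -> None:
        nonlocal motif_id, name, rows, open_record
        if motif_id is None:
            raise MotifParseError(f"line {lineno}: record without ID")
        if not rows:
            raise MotifParseError(f"record {motif_id}, line {lineno}: no count rows")
        matrices.append(PWMatrix(motif_id=motif_id, counts=np.array(rows), name=name))
        motif_id, name, rows, open_record = None, "", [], False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(("XX", "P0", "PO", "BF", "AC", "VV")):
            continue
        if line.startswith("//"):
            if open_record:
                flush(lineno)
            continue
        open_record = True
        tag, _, rest = line.partition(" ")
        if tag == "ID":
            if motif_id is not None:
                raise MotifParseError(
                    f"record {motif_id}, line {lineno}: duplicate ID before '//'"
                )
            motif_id = rest.strip()
        elif tag == "NA":
            name = rest.strip()
        elif tag[0].isdigit():
            fields = line.split()
            vals = fields[1:5]
            if len(vals) < 4:
                raise MotifParseError(
                    f"record {motif_id or '?'}, line {lineno}: "
                    f"expected 4 counts, got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError:
                raise MotifParseError(
                    f"record {motif_id or '?'}, line {lineno}: non-numeric count"
                ) from None
        # unrecognised tags are tolerated, as TRANSFAC carries many

    if open_record:
        raise MotifParseError(
            f"record {motif_id or '?'}: missing '//' terminator at end of file"
        )
    return matrices


def write_transfac(matrices: Iterable[PWMatrix], path) -> None:
    """Write matrices in the TRANSFAC flat-file layout read by parse_transfac."""
    with open(path, "w") as fh:
        for pwm in matrices:
            fh.write(f"ID  {pwm.motif_id}\n")
            if pwm.name:
                fh.write(f"NA  {pwm.name}\n")
            fh.write("P0      A      C      G      T\n")
            cons = pwm.consensus
            for i, row in enumerate(pwm.counts, start=1):
                cells = "  ".join(f"{v:7.2f}" for v in row)
                fh.write(f"{i:02d}  {cells}  {cons[i - 1]}\n")
            fh.write("XX\n//\n")
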