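"""PWM models of TF-family binding sites and consensus-filtered scanning.

The HSN TF collective comprises six transcription-factor families (ETS, POU,
Spalt, bHLH, Insm, GATA) whose binding preferences are modelled here as
position weight matrices built from aligned functional sites.  A candidate
site must pass two filters to count as a match: a relative PWM score of at
least ``min_rel_score`` (min–max normalised log-probability sum) and an exact
IUPAC consensus somewhere inside the matched window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC degenerate nucleotide classes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

#: Family consensus strings used for the exact-match specificity filter.
FAMILY_CONSENSUS = {
    "ETS": "YWTCCG",
    "GATA": "DGATAD",
    "HLH": "SCAGAA",
    "INSM": "CCSCWNNM",
    "SPALT": "TTGTST",
    "POU": "WTKCAT",
}

DEFAULT_MIN_REL_SCORE = 0.70
DEFAULT_PSEUDOCOUNT = 0.1


class AlignmentError(ValueError):
    """Raised when binding sites passed to :func:`build_pwm` are not aligned."""


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; IUPAC codes are complemented too."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"not a nucleotide code: {exc.args[0]!r}") from exc


def encode(seq: str) -> np.ndarray:
    """Encode DNA as int8: A,C,G,T -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class RegulatoryRegion:
    """An upstream or intronic sequence attached to a gene."""

    region_id: str
    gene_id: str
    kind: str  # "upstream" | "intronic"
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGTN"):
            raise ValueError(f"region {self.region_id}: non-ACGTN characters")
        if self.kind not in ("upstream", "intronic"):
            raise ValueError(f"region kind must be upstream/intronic, got {self.kind!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifMatch:
    """A scored, stranded PWM match inside one region (0-based half-open)."""

    family: str
    region_id: str
    start: int
    end: int
    strand: str
    rel_score: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.rel_score <= 1.0 + 1e-12:
            raise ValueError("rel_score outside [0, 1]")


@dataclass
class MotifModel:
    """A TF family's PWM plus its exact-consensus filter and score threshold.

    Parameters
    ----------
    family:
        Family label (one of the six collective members, extensible).
    matrix:
        (W, 4) per-position probabilities over A, C, G, T; each row sums to 1.
    consensus:
        IUPAC string of length <= W; a match must contain an exact instance of
        it at some offset of the matched window.
    min_rel_score:
        Minimum min–max-normalised log-probability score, default 0.70.
    """

    family: str
    matrix: np.ndarray
    consensus: str
    min_rel_score: float = DEFAULT_MIN_REL_SCORE
    _log: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (W, 4)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError("negative probabilities")
        self.consensus = self.consensus.upper()
        if len(self.consensus) > self.width:
            raise ValueError("consensus longer than PWM width")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC consensus symbols: {sorted(bad)}")
        if not 0.0 <= self.min_rel_score <= 1.0:
            raise ValueError("min_rel_score must lie in [0, 1]")
        with np.errstate(divide="ignore"):
            logm = np.log(self.matrix)
        # 5th column scores N as NaN so N-containing windows drop out.
        self._log = np.hstack([logm, np.full((self.width, 1), np.nan)])

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "MotifModel":
        """The same model read on the opposite strand."""
        rc_matrix = self.matrix[::-1, ::-1]
        return MotifModel(self.family, rc_matrix, reverse_complement(self.consensus),
                          self.min_rel_score)

    # -- scoring -----------------------------------------------------------

    def _score_bounds(self) -> tuple[float, float]:
        logm = self._log[:, :4]
        return float(logm.min(axis=1).sum()), float(logm.max(axis=1).sum())

    def rel_scores(self, codes: np.ndarray) -> np.ndarray:
        """Relative scores of every window of an encoded sequence.

        Returns an array of length ``len(codes) - W + 1``; windows containing
        N score NaN.  Scores are (S - S_min) / (S_max - S_min) for S the sum
        of per-position log-probabilities.
        """
        if np.any(self.matrix == 0):
            raise ValueError("PWM has zero entries; scan requires a pseudocount")
        w = self.width
        if len(codes) < w:
            return np.empty(0)
        n_win = len(codes) - w + 1
        scores = np.zeros(n_win, dtype=np.float64)
        for j in range(w):  # shifted table lookups beat a 2-D gather here
            scores += self._log[j].take(codes[j:j + n_win])
        smin, smax = self._score_bounds()
        if smax == smin:  # degenerate flat PWM
            return np.where(np.isnan(scores), np.nan, 1.0)
        return (scores - smin) / (smax - smin)


def build_pwm(
    sites: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    *,
    family: str = "motif",
    consensus: str | None = None,
    min_rel_score: float = DEFAULT_MIN_REL_SCORE,
) -> MotifModel:
    """Build a PWM from aligned functional binding sites.

    ``matrix[j, b] = (count of b at position j + pseudocount) /
    (n_sites + 4 * pseudocount)``.  ``consensus`` defaults to the family's
    entry in :data:`FAMILY_CONSENSUS`, else to an N-run the width of the PWM
    (i.e. no consensus constraint).
    """
    if not sites:
        raise ValueError("need at least one binding site")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise AlignmentError("binding sites must all have the same length")
    counts = np.zeros((width, 4))
    for site in sites:
        codes = encode(site)
        if np.any(codes == 4):
            raise ValueError("binding sites must be over {A,C,G,T}")
        counts[np.arange(width), codes] += 1
    matrix = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    if consensus is None:
        consensus = FAMILY_CONSENSUS.get(family, "N" * width)
    return MotifModel(family, matrix, consensus, min_rel_score)


def rel_score(model: MotifModel, window: str) -> float:
    """Relative score of one window of PWM width (no N allowed)."""
    if len(window) != model.width:
        raise ValueError("window length must equal PWM width")
    codes = encode(window)
    if np.any(codes == 4):
        raise ValueError("window contains N; score undefined")
    return float(model.rel_scores(codes)[0])


def matches_consensus(consensus: str, window: str) -> bool:
    """True iff the window contains an exact IUPAC instance of the consensus.

    The consensus may sit at any offset of the window (substring semantics).
    """
    consensus = consensus.upper()
    window = window.upper()
    classes = [IUPAC.get(sym) for sym in consensus]
    if any(c is None for c in classes):
        raise ValueError("invalid IUPAC symbol in consensus")
    c = len(consensus)
    for off in range(len(window) - c + 1):
        if all(window[off + j] in classes[j] for j in range(c)):
            return True
    return False


def _consensus_hits(codes: np.ndarray, consensus: str) -> np.ndarray:
    """Boolean array: position i starts an exact instance of the consensus."""
    c = len(consensus)
    n = len(codes)
    if n < c:
        return np.zeros(0, dtype=bool)
    table = np.zeros((c, 5), dtype=bool)
    for j, sym in enumerate(consensus):
        for b in IUPAC[sym]:
            table[j, BASE_INDEX[b]] = True
    hits = np.ones(n - c + 1, dtype=bool)
    for j in range(c):
        hits &= table[j, codes[j:n - c + 1 + j]]
    return hits


def _window_has_consensus(codes: np.ndarray, consensus: str, width: int) -> np.ndarray:
    """For each window start p, whether [p, p+width) contains the consensus."""
    c = len(consensus)
    n_win = len(codes) - width + 1
    if n_win <= 0:
        return np.zeros(0, dtype=bool)
    starts = _consensus_hits(codes, consensus)
    # window p passes iff any consensus start in [p, p + width - c]
    span = width - c + 1
    cum = np.zeros(len(starts) + span + 1, dtype=np.int32)
    np.cumsum(starts, out=cum[1:len(starts) + 1])
    cum[len(starts) + 1:] = cum[len(starts)]
    return (cum[span:span + n_win] - cum[:n_win]) > 0


def _scan_codes(model: MotifModel, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match positions and scores of one strand-oriented model.

    The exact-consensus filter is applied first (it is cheap and selective);
    only consensus-bearing windows are scored.  N-containing windows score
    NaN and are skipped.
    """
    if np.any(model.matrix == 0):
        raise ValueError("PWM has zero entries; scan requires a pseudocount")
    w = model.width
    if len(codes) < w:
        return np.empty(0, dtype=np.int64), np.empty(0)
    cand = np.nonzero(_window_has_consensus(codes, model.consensus, w))[0]
    if len(cand) == 0:
        return cand, np.empty(0)
    windows = codes[cand[:, None] + np.arange(w)[None, :]]
    scores = model._log[np.arange(w), windows].sum(axis=1)
    smin, smax = model._score_bounds()
    rel = ((scores - smin) / (smax - smin)) if smax > smin \
        else np.where(np.isnan(scores), np.nan, 1.0)
    with np.errstate(invalid="ignore"):
        keep = rel >= model.min_rel_score
    return cand[keep], rel[keep]


def scan_region(
    model: MotifModel,
    region: RegulatoryRegion,
    both_strands: bool = True,
) -> list[MotifMatch]:
    """All matches of one family in one region, both strands by default.

    A window is a match when its relative score reaches the model threshold
    and the (strand-oriented) matched sequence bears the exact consensus.
    Coordinates are always reported on the + strand of the region; minus
    strand matches are windows whose reverse complement satisfies the model.
    Windows containing N are skipped.
    """
    codes = encode(region.sequence)
    if len(codes) < model.width:
        return []
    out: list[MotifMatch] = []
    strand_models = [("+", model)]
    if both_strands:
        strand_models.append(("-", model.reverse_complement()))
    for strand, m in strand_models:
        positions, scores = _scan_codes(m, codes)
        for p, s in zip(positions, scores):
            out.append(MotifMatch(model.family, region.region_id,
                                  int(p), int(p) + model.width, strand,
                                  float(s)))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def scan_regions(
    models: Iterable[MotifModel],
    regions: Iterable[RegulatoryRegion],
    both_strands: bool = True,
) -> list[MotifMatch]:
    """Scan every region with every family model.

    Equivalent to concatenating :func:`scan_region` over the product but
    vectorised: regions are joined with N spacers (N windows never match)
    and each model/strand is scored in one pass over the joined sequence.
    """
    regions = list(regions)
    models = list(models)
    if not regions or not models:
        return []
    max_w = max(m.width for m in models)
    spacer = np.full(max_w, 4, dtype=np.int8)
    pieces: list[np.ndarray] = []
    offsets: list[int] = []
    pos = 0
    for r in regions:
        offsets.append(pos)
        codes = encode(r.sequence)
        pieces.append(codes)
        pieces.append(spacer)
        pos += len(codes) + max_w
    genome = np.concatenate(pieces)
    offsets_arr = np.asarray(offsets)

    out: list[MotifMatch] = []
    for model in models:
        strand_models = [("+", model)]
        if both_strands:
            strand_models.append(("-", model.reverse_complement()))
        for strand, m in strand_models:
            hits, scores = _scan_codes(m, genome)
            ridx = np.searchsorted(offsets_arr, hits, side="right") - 1
            for p, ri, s in zip(hits, ridx, scores):
                region = regions[ri]
                start = int(p) - offsets[ri]
                # windows straddling a spacer contain N and never match
                out.append(MotifMatch(model.family, region.region_id,
                                      start, start + model.width, strand,
                                      float(s)))
    out.sort(key=lambda m: (m.region_id, m.family, m.start, m.strand))
    return out
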