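"""Position-frequency signature models over Down-Seq alignment blocks.

Subtype-specific amino-acid signatures live in two or three short windows
(WL1, WL2, optional WL3) of the Down-Seq region; WL1/WL2 coincide with the
classical C6/C7 (E6/E7) core motifs of the condensation superfamily.  This
module turns aligned Down-Seq blocks into position frequency matrices
(PFMs), computes sequence-logo information content with the standard
small-sample correction, renders degenerate text signatures (majority
residues in capitals, alternatives bracketed), and scores query windows by
log-odds against a background distribution.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .archmodel import DomainToken, normalize_token

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
GAP = "-"
LOG2_20 = math.log2(20.0)


def uniform_background() -> np.ndarray:
    """Uniform residue distribution (1/20 each), the default background."""
    return np.full(20, 0.05)


#: Robinson–Robinson amino-acid frequencies (optional background).
ROBINSON_BACKGROUND = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)


class BlockError(ValueError):
    """Raised for ragged or empty alignment blocks."""


@dataclass
class AlignedBlock:
    """Equal-length gapped sequences sharing one subtype label."""

    subtype: DomainToken
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise BlockError("empty alignment block")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise BlockError("ragged rows in alignment block")
        allowed = set(AA_ALPHABET) | {GAP, "X"}
        for r in self.rows:
            bad = set(r.upper()) - allowed
            if bad:
                raise BlockError(f"invalid characters in block: {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class PFM:
    """Per-column amino-acid frequencies with effective (non-gap) counts."""

    freqs: np.ndarray  # (L, 20), rows sum to 1
    counts: np.ndarray  # (L,) effective non-gap counts
    gap_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 20 or len(self.freqs) < 1:
            raise BlockError("PFM must be an L x 20 matrix with L >= 1")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise BlockError("PFM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.freqs.argmax(axis=1))

    def slice(self, start: int, end: int) -> "PFM":
        gf = None if self.gap_fraction is None else self.gap_fraction[start:end]
        return PFM(self.freqs[start:end], self.counts[start:end], gf)


def column_frequencies(
    block: AlignedBlock,
    alpha: float = 0.5,
    background: np.ndarray | None = None,
) -> PFM:
    """Column-wise residue frequencies with background-distributed pseudocounts.

    ``freq(a, i) = (count(a, i) + alpha * bg(a)) / (nongap(i) + alpha)``; gap
    (and X) mass is excluded from the numerator and reported separately as
    a gap fraction.
    """
    if alpha < 0:
        raise ValueError("pseudocount alpha must be >= 0")
    bg = uniform_background() if background is None else np.asarray(background, float)
    L = block.length
    counts = np.zeros((L, 20))
    for row in block.rows:
        for i, ch in enumerate(row):
            j = _AA_INDEX.get(ch)
            if j is not None:
                counts[i, j] += 1
    nongap = counts.sum(axis=1)
    denom = nongap + alpha
    if np.any(denom == 0):
        raise BlockError("column with no residues and zero pseudocount")
    freqs = (counts + alpha * bg) / denom[:, None]
    # renormalize away rounding error so columns sum to exactly 1
    freqs /= freqs.sum(axis=1, keepdims=True)
    gap_fraction = 1.0 - nongap / block.n
    return PFM(freqs, nongap, gap_fraction)


@dataclass(frozen=True)
class LogoColumn:
    """Sequence-logo content of one column: R bits split into letter heights."""

    R: float
    heights: dict[str, float]
    e_n: float


def information_content(freqs_column: np.ndarray, n: int) -> LogoColumn:
    """Schneider–Stephens information content with small-sample correction.

    ``H = -sum f log2 f``; ``e_n = 19 / (2 ln2 n)``; ``R = max(0, log2 20 -
    H - e_n)``; letter heights are ``f * R`` so they always sum to R.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    f = np.asarray(freqs_column, dtype=float)
    nz = f[f > 0]
    H = float(-(nz * np.log2(nz)).sum())
    e_n = 19.0 / (2.0 * math.log(2.0) * n)
    R = max(0.0, LOG2_20 - H - e_n)
    heights = {AA_ALPHABET[i]: float(f[i] * R) for i in range(20) if f[i] > 0}
    return LogoColumn(R=R, heights=heights, e_n=e_n)


def logo_columns(pfm: PFM, n: int) -> list[LogoColumn]:
    return [information_content(pfm.freqs[i], n) for i in range(pfm.length)]


def export_logo_tsv(pfm: PFM, n: int, path: str | Path) -> None:
    """Write per-column logo data (position, R, letter heights) as TSV."""
    cols = logo_columns(pfm, n)
    with open(path, "w") as fh:
        fh.write("position\tR_bits\t" + "\t".join(AA_ALPHABET) + "\n")
        for i, col in enumerate(cols, start=1):
            heights = "\t".join(
                f"{col.heights.get(a, 0.0):.6g}" for a in AA_ALPHABET
            )
            fh.write(f"{i}\t{col.R:.6g}\t{heights}\n")


# --- degenerate text signatures -------------------------------------------

_POSITION_RE = re.compile(r"(?:([A-Z])|\(([A-Z]{2,})\)|x)(?:\[([A-Z]+)\])?")


@dataclass
class DegenerateSignature:
    """Per-position majority residues (capitals) and bracketed alternatives.

    Rendering: one major residue appears as a capital letter, several
    majors are parenthesized, a position with no major is ``x``; bracketed
    alternatives follow, e.g. ``Hx[LM]D``.  Render/parse round-trips.
    """

    positions: list[tuple[tuple[str, ...], tuple[str, ...]]]

    def render(self) -> str:
        out = []
        for majors, alts in self.positions:
            if not majors:
                s = "x"
            elif len(majors) == 1:
                s = majors[0]
            else:
                s = "(" + "".join(majors) + ")"
            if alts:
                s += "[" + "".join(alts) + "]"
            out.append(s)
        return "".join(out)

    @classmethod
    def parse(cls, text: str) -> "DegenerateSignature":
        positions = []
        pos = 0
        while pos < len(text):
            m = _POSITION_RE.match(text, pos)
            if not m or m.start() != pos:
                raise ValueError(f"cannot parse signature {text!r} at offset {pos}")
            single, multi, alts = m.groups()
            majors = tuple(single) if single else tuple(multi) if multi else ()
            positions.append((majors, tuple(alts) if alts else ()))
            pos = m.end()
        return cls(positions)


def make_signature(
    pfm: PFM, theta_major: float = 0.5, theta_alt: float = 0.15
) -> DegenerateSignature:
    """Threshold a PFM into a degenerate signature.

    Majors are residues with frequency >= ``theta_major``; alternatives fall
    in ``[theta_alt, theta_major)``; a position with neither is a wildcard.
    """
    if not (0 < theta_alt <= theta_major <= 1):
        raise ValueError("require 0 < theta_alt <= theta_major <= 1")
    positions = []
    for col in pfm.freqs:
        majors = tuple(AA_ALPHABET[i] for i in range(20) if col[i] >= theta_major)
        alts = tuple(
            AA_ALPHABET[i] for i in range(20) if theta_alt <= col[i] < theta_major
        )
        positions.append((majors, alts))
    return DegenerateSignature(positions)


# --- window scoring --------------------------------------------------------


def score_window(
    query_window: str,
    window_pfm: PFM,
    background: np.ndarray | None = None,
    floor: float = 1e-3,
    gap_penalty: float = -2.0,
) -> float:
    """Log-odds score (bits) of a query window against a window PFM.

    ``sum_i log2(f(q_i, i) / bg(q_i))`` with frequencies floored at
    ``floor``; X residues contribute 0 bits and gap characters a fixed
    penalty.
    """
    if len(query_window) != window_pfm.length:
        raise ValueError(
            f"query length {len(query_window)} != window length {window_pfm.length}"
        )
    bg = uniform_background() if background is None else np.asarray(background, float)
    score = 0.0
    for i, ch in enumerate(query_window.upper()):
        if ch == "X":
            continue
        if ch == GAP:
            score += gap_penalty
            continue
        j = _AA_INDEX.get(ch)
        if j is None:
            raise ValueError(f"invalid residue {ch!r} in query window")
        score += math.log2(max(window_pfm.freqs[i, j], floor) / bg[j])
    return score


def _score_profile(
    seq: str, window_pfm: PFM, bg: np.ndarray, floor: float, gap_penalty: float
) -> np.ndarray:
    """Scores of the window at every offset of ``seq`` (vectorized scan)."""
    L = window_pfm.length
    n = len(seq) - L + 1
    if n < 1:
        raise ValueError(f"sequence shorter ({len(seq)}) than window ({L})")
    logodds = np.log2(np.maximum(window_pfm.freqs, floor) / bg[None, :])  # (L, 20)
    s = seq.upper()
    codes = np.array([_AA_INDEX.get(c, -1) for c in s])
    is_gap = np.array([c == GAP for c in s])
    contrib = np.zeros((len(s), L))
    valid = codes >= 0
    for i in range(L):
        contrib[valid, i] = logodds[i, codes[valid]]
        contrib[is_gap, i] = gap_penalty
    out = np.empty(n)
    for o in range(n):
        out[o] = contrib[np.arange(o, o + L), np.arange(L)].sum()
    return out


def locate_best_window(
    downseq_sequence: str,
    window_pfm: PFM,
    background: np.ndarray | None = None,
    floor: float = 1e-3,
    gap_penalty: float = -2.0,
) -> tuple[int, float]:
    """Best-scoring offset of a window in a Down-Seq; ties go leftmost."""
    bg = uniform_background() if background is None else np.asarray(background, float)
    prof = _score_profile(downseq_sequence, window_pfm, bg, floor, gap_penalty)
    off = int(prof.argmax())  # argmax returns the first (leftmost) maximum
    return off, float(prof[off])


def locate_windows_ordered(
    downseq_sequence: str,
    window_pfms: list[PFM],
    background: np.ndarray | None = None,
    floor: float = 1e-3,
    gap_penalty: float = -2.0,
) -> tuple[list[tuple[int, float]], float]:
    """Jointly place ordered, non-overlapping windows maximizing total score.

    Windows must appear in order (WL1 before WL2 before WL3); the optimal
    placement is found by dynamic programming over offsets, with ties
    resolved toward the smallest offsets.
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    profiles = [
        _score_profile(downseq_sequence, pfm, bg, floor, gap_penalty)
        for pfm in window_pfms
    ]
    lengths = [pfm.length for pfm in window_pfms]
    if sum(lengths) > len(downseq_sequence):
        raise ValueError("windows do not fit in sequence under the ordering constraint")
    k = len(profiles)
    n = len(downseq_sequence)
    # best[j][o] = best total for windows j..k-1 with window j at offset >= o
    # suffix_max[j][o] = max over o' >= o of (profiles[j][o'] + tail), tail
    # constrained so window j+1 starts at or after o' + lengths[j].
    best = [None] * k
    best[k - 1] = profiles[k - 1]
    for j in range(k - 2, -1, -1):
        nxt = best[j + 1]
        # tail_max[o] = max over o' >= o of nxt[o']
        tail_max = np.maximum.accumulate(nxt[::-1])[::-1]
        nj = len(profiles[j])
        vals = np.full(nj, -np.inf)
        for o in range(nj):
            start_next = o + lengths[j]
            if start_next < len(nxt):
                vals[o] = profiles[j][o] + tail_max[start_next]
        best[j] = vals
    total = float(np.max(best[0]))
    # greedy left-to-right reconstruction (argmax picks leftmost tie)
    placements: list[tuple[int, float]] = []
    min_off = 0
    for j in range(k):
        vals = best[j][min_off:]
        o = min_off + int(np.argmax(vals))
        placements.append((o, float(profiles[j][o])))
        min_off = o + lengths[j]
    return placements, total


# --- signature models ------------------------------------------------------

#: Number of signature windows per subtype: C-starter and Ct carry two
#: (WL1, WL2); LCL, DCL, dual C/E and E carry three (WL1, WL2, WL3).
WINDOWS_PER_SUBTYPE = {
    DomainToken.CSTARTER: 2,
    DomainToken.CT: 2,
    DomainToken.LCL: 3,
    DomainToken.DCL: 3,
    DomainToken.CE: 3,
    DomainToken.E: 3,
}


@dataclass
class SignatureModel:
    """Per-subtype ordered signature windows over a background distribution."""

    subtype: DomainToken
    windows: list[tuple[str, PFM]]  # [("WL1", pfm), ...] in sequence order
    background: np.ndarray = field(default_factory=uniform_background)
    n_training: int = 0

    def __post_init__(self) -> None:
        expected = WINDOWS_PER_SUBTYPE.get(self.subtype)
        if expected is not None and len(self.windows) != expected:
            raise ValueError(
                f"{self.subtype} model must have {expected} windows, "
                f"got {len(self.windows)}"
            )

    @property
    def window_pfms(self) -> list[PFM]:
        return [pfm for _, pfm in self.windows]

    @property
    def min_sequence_length(self) -> int:
        return sum(p.length for p in self.window_pfms)

    def consensus_score(self, floor: float = 1e-3) -> float:
        """Score of each window's own consensus: the model's ceiling."""
        return sum(
            score_window(pfm.consensus(), pfm, self.background, floor=floor)
            for pfm in self.window_pfms
        )

    def scan(self, downseq_sequence: str, **kwargs) -> tuple[list[tuple[int, float]], float]:
        return locate_windows_ordered(
            downseq_sequence, self.window_pfms, self.background, **kwargs
        )

    def to_dict(self) -> dict:
        return {
            "subtype": str(self.subtype),
            "background": self.background.tolist(),
            "n_training": self.n_training,
            "windows": [
                {
                    "name": name,
                    "freqs": pfm.freqs.tolist(),
                    "counts": pfm.counts.tolist(),
                }
                for name, pfm in self.windows
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        windows = [
            (w["name"], PFM(np.array(w["freqs"]), np.array(w["counts"])))
            for w in d["windows"]
        ]
        return cls(
            subtype=normalize_token(d["subtype"]),
            windows=windows,
            background=np.array(d["background"]),
            n_training=int(d.get("n_training", 0)),
        )


def find_signature_windows(
    pfm: PFM, n: int, n_windows: int, window_len: int = 12
) -> list[int]:
    """Pick ordered, non-overlapping windows of maximal information content.

    Used when training from a full-length aligned Down-Seq block: the
    per-column logo information R is summed over candidate windows and the
    non-overlapping combination with the largest total is selected by
    dynamic programming (leftmost on ties).
    """
    R = np.array([information_content(pfm.freqs[i], max(n, 1)).R for i in range(pfm.length)])
    win_sums = np.convolve(R, np.ones(window_len), mode="valid")
    m = len(win_sums)
    if m < 1 or pfm.length < n_windows * window_len:
        raise BlockError("block too short for the requested signature windows")
    best = np.full((n_windows, m), -np.inf)
    best[n_windows - 1] = win_sums
    for j in range(n_windows - 2, -1, -1):
        tail = np.maximum.accumulate(best[j + 1][::-1])[::-1]
        for o in range(m):
            nxt = o + window_len
            if nxt < m:
                best[j, o] = win_sums[o] + tail[nxt]
    offsets = []
    min_off = 0
    for j in range(n_windows):
        o = min_off + int(np.argmax(best[j][min_off:]))
        offsets.append(o)
        min_off = o + window_len
    return offsets


def train_model(
    block: AlignedBlock,
    n_windows: int | None = None,
    window_len: int = 12,
    alpha: float = 0.5,
    background: np.ndarray | None = None,
) -> SignatureModel:
    """Train a subtype signature model from an aligned Down-Seq block.

    The full block is reduced to a PFM, the highest-information windows are
    located, and their PFM slices become the model's WL windows.
    """
    bg = uniform_background() if background is None else np.asarray(background, float)
    if n_windows is None:
        n_windows = WINDOWS_PER_SUBTYPE.get(block.subtype, 3)
    full = column_frequencies(block, alpha=alpha, background=bg)
    offsets = find_signature_windows(full, block.n, n_windows, window_len)
    windows = [
        (f"WL{i + 1}", full.slice(o, o + window_len)) for i, o in enumerate(offsets)
    ]
    return SignatureModel(block.subtype, windows, bg, n_training=block.n)


def save_models(models: dict[DomainToken, SignatureModel], path: str | Path) -> None:
    payload = {str(k): m.to_dict() for k, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_models(path: str | Path) -> dict[DomainToken, SignatureModel]:
    payload = json.loads(Path(path).read_text())
    return {
        normalize_token(k): SignatureModel.from_dict(v) for k, v in payload.items()
    }
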