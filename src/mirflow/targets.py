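"""Plant miRNA target prediction by complementarity penalty scoring.

Each transcript window the length of the miRNA is aligned antiparallel and
gaplessly against the miRNA and scored position by position (miRNA
positions numbered from its 5' end): mismatch 1.0, G:U wobble 0.5, with
contributions at positions 2-13 doubled.  Windows at or below the penalty
threshold (default 4.0) are reported.  Optional positional constraints
flag sites with any mismatch opposite miRNA positions 10-11 (the expected
cleavage site) or more than one mismatch across positions 2-12; G:U
wobbles contribute penalty but are not counted as mismatches by the
positional flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import read_fasta, to_dna, validate_alphabet

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0  # reserved: alignment is gapless by default
CORE_START, CORE_END = 2, 13  # doubled-penalty zone, 1-based inclusive
CLEAVAGE_POSITIONS = (10, 11)
SEED_REGION = (2, 12)
DEFAULT_MAX_PENALTY = 4.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# Watson-Crick partners in DNA alphabet (U stored as T)
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U wobble


@dataclass(frozen=True)
class TargetSite:
    """A predicted target site on a transcript (0-based half-open)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    penalty: float
    alignment: tuple[str, str, str]  # miRNA 3'->5', pairing row, target 5'->3'
    flags: tuple[str, ...]


def _pair_class(mirna_base: str, target_base: str) -> str:
    if (mirna_base, target_base) in _WC:
        return "match"
    if (mirna_base, target_base) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _position_weight(pos_1based: int) -> float:
    return 2.0 if CORE_START <= pos_1based <= CORE_END else 1.0


def score_duplex_penalty(
    mirna: str, window: str
) -> tuple[float, tuple[str, ...]]:
    """Penalty and constraint flags for one miRNA/window alignment.

    ``window`` is the transcript region 5'->3'; it must be at least as
    long as the miRNA.  When longer, every gapless offset is scored and
    the best (lowest-penalty) one is returned.
    """
    mirna = to_dna(mirna)
    window = to_dna(window)
    validate_alphabet(mirna)
    validate_alphabet(window)
    if len(window) < len(mirna):
        raise ValueError("target window shorter than miRNA")
    best: tuple[float, tuple[str, ...]] | None = None
    for off in range(len(window) - len(mirna) + 1):
        pen, flags = _score_at(mirna, window[off : off + len(mirna)])
        if best is None or pen < best[0]:
            best = (pen, flags)
    return best


def _score_at(mirna: str, window: str) -> tuple[float, tuple[str, ...]]:
    L = len(mirna)
    penalty = 0.0
    mismatches_in_seed = 0
    cleavage_hit = False
    for i, mb in enumerate(mirna):  # i: 0-based from miRNA 5' end
        tb = window[L - 1 - i]  # antiparallel pairing
        cls = _pair_class(mb, tb)
        pos = i + 1
        if cls == "mismatch":
            penalty += MISMATCH_PENALTY * _position_weight(pos)
            if SEED_REGION[0] <= pos <= SEED_REGION[1]:
                mismatches_in_seed += 1
            if pos in CLEAVAGE_POSITIONS:
                cleavage_hit = True
        elif cls == "wobble":
            penalty += WOBBLE_PENALTY * _position_weight(pos)
    flags = []
    if cleavage_hit:
        flags.append("cleavage_site_mismatch")
    if mismatches_in_seed > 1:
        flags.append("seed_mismatches")
    return penalty, tuple(flags)


def _alignment_strings(mirna: str, window: str) -> tuple[str, str, str]:
    L = len(mirna)
    mir_row = mirna[::-1]  # 3'->5', lines up with target 5'->3'
    pairing = []
    for j, tb in enumerate(window):
        mb = mir_row[j]
        cls = _pair_class(mb, tb)
        pairing.append("|" if cls == "match" else "o" if cls == "wobble" else " ")
    return mir_row, "".join(pairing), window[:L]


def _penalty_tables(mirna: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(window position, target base) lookup tables for the scan."""
    L = len(mirna)
    pen = np.zeros((L, 5))
    seed_mm = np.zeros((L, 5))
    cleave_mm = np.zeros((L, 5))
    for j in range(L):  # window position j pairs miRNA position L-1-j
        i = L - 1 - j
        pos = i + 1
        w = _position_weight(pos)
        for tb, b in _BASE_INDEX.items():
            cls = _pair_class(mirna[i], tb) if tb != "N" else "mismatch"
            if cls == "mismatch":
                pen[j, b] = MISMATCH_PENALTY * w
                if SEED_REGION[0] <= pos <= SEED_REGION[1]:
                    seed_mm[j, b] = 1
                if pos in CLEAVAGE_POSITIONS:
                    cleave_mm[j, b] = 1
            elif cls == "wobble":
                pen[j, b] = WOBBLE_PENALTY * w
    return pen, seed_mm, cleave_mm


def scan_transcript(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    max_penalty: float = DEFAULT_MAX_PENALTY,
    enforce_flags: bool = False,
) -> list[TargetSite]:
    """All windows of one transcript with penalty <= max_penalty."""
    mirna = to_dna(mirna)
    seq = to_dna(transcript)
    L = len(mirna)
    if len(seq) < L:
        return []
    pen_t, seed_t, cleave_t = _penalty_tables(mirna)
    enc = np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    idx = np.arange(L)
    penalties = pen_t[idx, windows].sum(axis=1)
    keep = np.flatnonzero(penalties <= max_penalty + 1e-9)
    sites = []
    for o in keep:
        o = int(o)
        window = seq[o : o + L]
        flags = []
        if cleave_t[idx, windows[o]].sum() > 0:
            flags.append("cleavage_site_mismatch")
        if seed_t[idx, windows[o]].sum() > 1:
            flags.append("seed_mismatches")
        if enforce_flags and flags:
            continue
        sites.append(
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=o,
                end=o + L,
                penalty=float(penalties[o]),
                alignment=_alignment_strings(mirna, window),
                flags=tuple(flags),
            )
        )
    sites.sort(key=lambda s: (s.penalty, s.start))
    return sites


def scan_transcripts(
    mirna_id: str,
    mirna: str,
    transcripts: dict[str, str] | str,
    max_penalty: float = DEFAULT_MAX_PENALTY,
    enforce_flags: bool = False,
) -> list[TargetSite]:
    """Scan a transcript set (dict or FASTA path); deterministic order.

    Sites are sorted by penalty, then transcript id, then coordinate.  An
    empty FASTA yields an empty result.
    """
    if isinstance(transcripts, (str, bytes)) or hasattr(transcripts, "__fspath__"):
        transcripts = read_fasta(transcripts)
    sites: list[TargetSite] = []
    for tid, seq in transcripts.items():
        sites.extend(
            scan_transcript(mirna_id, mirna, tid, seq, max_penalty, enforce_flags)
        )
    sites.sort(key=lambda s: (s.penalty, s.transcript_id, s.start))
    return sites


def sites_to_frame(sites: list[TargetSite]):
    import pandas as pd

    return pd.DataFrame(
        [
            (
                s.mirna_id,
                s.transcript_id,
                s.start,
                s.end,
                s.penalty,
                " / ".join(s.alignment),
                ";".join(s.flags),
            )
            for s in sites
        ],
        columns=["mirna_id", "transcript", "start", "end", "penalty", "alignment", "flags"],
    )
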