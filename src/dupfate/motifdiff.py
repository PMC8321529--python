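"""PWM scanning and paralog-specific motif gain/loss comparison.

Scores are log-odds base 2 against a background model, discretized to a fixed
granularity so that the exact p-value dynamic program and the per-window
scores live in the same integer space (the DP is then exact, not an
approximation).  Matches are kept at a BH FDR threshold per (motif, sequence)
scan; hit sets from homologous sequences are anchored through pairwise
alignments to a common reference and classified as shared, paralog-specific
gains, or paralog-specific losses, with polarity taken from the outgroup
ortholog.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from dupfate.multitest import bh_adjust

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")
SCORE_GRANULARITY = 1e-3
PROB_FLOOR = 1e-10  # avoids -inf log-odds for hard zeros in a PWM
DEFAULT_SITE_WINDOW = 3


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # positions x 4 probabilities (A, C, G, T)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if self.matrix.shape[0] < 2:
            raise ValueError("PWM must span >=2 positions")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-4):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def int_scores(self) -> np.ndarray:
        """Per-position integer log-odds (units of SCORE_GRANULARITY)."""
        p = np.clip(self.matrix, PROB_FLOOR, None)
        b = np.clip(self.background, PROB_FLOOR, None)
        lo = np.log2(p / b)
        return np.round(lo / SCORE_GRANULARITY).astype(np.int64)

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass
class MotifHit:
    sequence_id: str
    motif_id: str
    start: int  # 0-based on the forward strand
    strand: str
    score: float
    p: float
    q: float = float("nan")


@dataclass
class HomologComparison:
    motif_id: str
    anchor: int | None  # reference coordinate of the site
    status: dict  # homolog id -> "present" | "absent"
    classification: str  # shared | paralog_specific_gain | paralog_specific_loss | unpolarized
    affected: tuple = ()


def parse_meme_minimal(text: str) -> list[PWM]:
    """Parse motifs from MEME minimal format text."""
    lines = text.splitlines()
    background = np.full(4, 0.25)
    motifs = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            fields = lines[i].split()
            freqs = dict(zip(fields[0::2], [float(x) for x in fields[1::2]]))
            background = np.array([freqs.get(b, 0.25) for b in ALPHABET])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith("letter-probability"):
                i += 1
            header = lines[i]
            width = None
            if "w=" in header:
                width = int(header.split("w=")[1].split()[0])
            rows = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                    except ValueError:
                        break
                    i += 1
                    if width is not None and len(rows) == width:
                        break
                else:
                    break
            motifs.append(PWM(motif_id, np.array(rows), background.copy()))
        i += 1
    return motifs


def write_meme_minimal(motifs: list[PWM]) -> str:
    out = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    if motifs:
        bg = motifs[0].background
        out += [
            "Background letter frequencies",
            " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
            "",
        ]
    for m in motifs:
        out.append(f"MOTIF {m.motif_id}")
        out.append(
            f"letter-probability matrix: alength= 4 w= {len(m)} nsites= 20 E= 0"
        )
        for row in m.matrix:
            out.append(" ".join(f"{x:.6f}" for x in row))
        out.append("")
    return "\n".join(out) + "\n"


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int64)
    for i, base in enumerate(ALPHABET):
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return codes


def _window_scores(codes: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing N score INT_MIN."""
    k, n = int_scores.shape[0], codes.size
    if k > n:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for off in range(k):
        c = codes[off : off + n - k + 1]
        valid &= c >= 0
        out += int_scores[off, np.where(c >= 0, c, 0)]
    out[~valid] = np.iinfo(np.int64).min
    return out


def score_pvalue_table(pwm: PWM):
    """Exact null distribution of integer window scores under the background.

    Returns (sorted unique scores, P(score >= s)) computed by dynamic
    programming over motif positions; exact because scanning uses the same
    integer scores.
    """
    int_scores = pwm.int_scores()
    bg = np.clip(pwm.background, PROB_FLOOR, None)
    bg = bg / bg.sum()
    dist = {0: 1.0}
    for pos in range(int_scores.shape[0]):
        new: dict[int, float] = defaultdict(float)
        for s, pr in dist.items():
            for b in range(4):
                new[s + int(int_scores[pos, b])] += pr * bg[b]
        dist = dict(new)
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]
    return scores, np.minimum(tail, 1.0)


def _pvalues(window_scores: np.ndarray, table) -> np.ndarray:
    scores, tail = table
    idx = np.searchsorted(scores, window_scores, side="left")
    p = np.where(idx < scores.size, tail[np.minimum(idx, scores.size - 1)], 0.0)
    # scores above the max possible cannot occur; scores below min get p=1
    return np.clip(p, None, 1.0)


def scan_pwm(
    sequence: str,
    pwm: PWM,
    alpha: float = 0.05,
    sequence_id: str = "seq",
    keep_all: bool = False,
) -> list[MotifHit]:
    """Scan both strands, assign exact p-values, BH-filter at ``alpha`` FDR.

    Returns significant hits (q < alpha) sorted by position, or every scored
    window when ``keep_all`` is set.  Windows containing N are skipped.
    """
    if not set(sequence.upper()) <= set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    codes = _encode(sequence)
    table = score_pvalue_table(pwm)
    k = len(pwm)
    hits = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        ws = _window_scores(codes, mat.int_scores())
        valid = ws != np.iinfo(np.int64).min
        ps = _pvalues(ws[valid], table)
        for start, s, p in zip(np.nonzero(valid)[0], ws[valid], ps):
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    motif_id=pwm.motif_id,
                    start=int(start),
                    strand=strand,
                    score=float(s) * SCORE_GRANULARITY,
                    p=float(p),
                )
            )
    qs = bh_adjust([h.p for h in hits])
    for h, q in zip(hits, qs):
        h.q = float(q)
    if not keep_all:
        hits = [h for h in hits if h.q < alpha]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def tf_expression_filter(tf_tpm, tpm_threshold: float = 1.0, fraction: float = 0.75):
    """Keep TFs expressed above ``tpm_threshold`` TPM in more than
    ``fraction`` of libraries (strict inequalities on both sides).

    ``tf_tpm`` is a DataFrame-like with TFs as rows and libraries as columns.
    """
    if tf_tpm.shape[0] == 0 or tf_tpm.shape[1] == 0:
        raise ValueError("empty TF expression matrix")
    above = (tf_tpm > tpm_threshold).sum(axis=1) / tf_tpm.shape[1]
    return list(tf_tpm.index[above > fraction])


def map_to_reference(pos: int, ref_aligned: str, alt_aligned: str) -> int | None:
    """Map an ungapped position in ``alt`` to the ungapped reference
    coordinate via their pairwise alignment; None when inside a reference gap."""
    alt_i = -1
    ref_i = -1
    for ra, aa in zip(ref_aligned, alt_aligned):
        if ra != "-":
            ref_i += 1
        if aa != "-":
            alt_i += 1
            if alt_i == pos:
                return ref_i if ra != "-" else None
    return None


def compare_homologs(
    hits_by_homolog: dict,
    alignments: dict,
    ortholog_id: str,
    site_window: int = DEFAULT_SITE_WINDOW,
) -> list[HomologComparison]:
    """Classify motif sites as shared or paralog-specific gains/losses.

    ``hits_by_homolog`` maps homolog id -> list of MotifHit; ``alignments``
    maps homolog id -> (reference_aligned, homolog_aligned) gapped strings
    against a common reference homolog (the reference maps to itself and may
    be omitted).  Hits of the same motif whose reference anchors are within
    +/-``site_window`` columns are treated as one site.  Polarity comes from
    the ortholog: a site present only in paralogs (ortholog absent) is a gain
    in those paralogs; a site present in the ortholog and at least one other
    homolog but absent from some paralog is a loss in that paralog.  Hits that
    fall in a reference gap cannot be anchored and are reported with a None
    anchor, excluded from gain/loss calls.
    """
    homologs = sorted(hits_by_homolog)
    if ortholog_id not in homologs:
        raise ValueError("ortholog hits are required to polarize gains/losses")
    anchored = []  # (motif, anchor, homolog)
    unanchored = []
    for hom in homologs:
        for hit in hits_by_homolog[hom]:
            if hom in alignments:
                ref_a, alt_a = alignments[hom]
                anchor = map_to_reference(hit.start, ref_a, alt_a)
            else:
                anchor = hit.start  # reference homolog
            if anchor is None:
                unanchored.append((hit.motif_id, hom))
            else:
                anchored.append((hit.motif_id, anchor, hom))

    comparisons = []
    by_motif: dict[str, list] = defaultdict(list)
    for motif, anchor, hom in anchored:
        by_motif[motif].append((anchor, hom))
    for motif, sites in sorted(by_motif.items()):
        sites.sort()
        clusters: list[list] = []
        for anchor, hom in sites:
            if clusters and anchor - clusters[-1][-1][0] <= site_window:
                clusters[-1].append((anchor, hom))
            else:
                clusters.append([(anchor, hom)])
        for cluster in clusters:
            present = {hom for _, hom in cluster}
            status = {h: ("present" if h in present else "absent") for h in homologs}
            paralogs = [h for h in homologs if h != ortholog_id]
            absent_paralogs = tuple(h for h in paralogs if h not in present)
            present_paralogs = tuple(h for h in paralogs if h in present)
            if not absent_paralogs and ortholog_id in present:
                cls, affected = "shared", ()
            elif ortholog_id not in present:
                cls, affected = "paralog_specific_gain", present_paralogs
            elif present_paralogs:
                cls, affected = "paralog_specific_loss", absent_paralogs
            else:
                # ortholog-only site: not polarizable as paralog gain/loss
                cls, affected = "unpolarized", ()
            comparisons.append(
                HomologComparison(
                    motif_id=motif,
                    anchor=min(a for a, _ in cluster),
                    status=status,
                    classification=cls,
                    affected=affected,
                )
            )
    for motif, hom in unanchored:
        comparisons.append(
            HomologComparison(
                motif_id=motif,
                anchor=None,
                status={hom: "present"},
                classification="unanchored",
                affected=(),
            )
        )
    return comparisons
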