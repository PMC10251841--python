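"""PWM scanning, motif enrichment and Tn5 footprint classification.

A transcription factor bound to its motif shields that DNA from Tn5
insertion, so an *active* (DNA-bound) TF leaves a localised dip — a
footprint — in the aggregated cut-site profile around its motif
occurrences, while a merely enriched but unbound motif shows a flat or
disordered profile.  This module scores motifs with log-odds PWM
scanning, tests motif over-representation in target vs background
sequences, aggregates strand-oriented cut profiles around motif
centres, and classifies TFs as active/inactive from the footprint
depth, optionally cross-checking the call against RNA-seq expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PWM",
    "MotifOccurrence",
    "MotifSite",
    "FootprintProfile",
    "read_pwm",
    "write_pwm",
    "read_fasta",
    "pwm_scan",
    "motif_enrichment",
    "aggregate_footprint",
    "classify_active",
    "crosscheck_expression",
    "reverse_complement",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix (motif length x 4, columns A,C,G,T)."""

    name: str
    matrix: np.ndarray = field(repr=False)
    pseudocount: float = 0.001

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be length x 4")
        if m.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """log2 odds vs background (uniform 0.25 by default), with pseudocount."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = (self.matrix + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(probs / bg)

    def max_score(self, background: np.ndarray | None = None) -> float:
        return float(self.log_odds(background).max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1], self.pseudocount)


@dataclass(frozen=True)
class MotifOccurrence:
    """A PWM hit within a scanned sequence (position = window start)."""

    position: int
    strand: str
    score: float


@dataclass(frozen=True)
class MotifSite:
    """A motif occurrence in genomic coordinates."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FootprintProfile:
    """Aggregated cut counts around motif centres and the depth score.

    ``counts[window + off]`` is the total cut count at strand-oriented
    offset ``off`` from the motif centre, summed over sites.
    ``depth_score`` is mean(flank) / mean(centre), centre mean floored at
    1 to avoid division by zero.
    """

    tf_name: str
    window: int
    counts: np.ndarray = field(repr=False)
    n_sites: int
    motif_length: int
    depth_score: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("profile requires >= 1 site")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")


# ---------------------------------------------------------------------------
# PWM I/O and scanning
# ---------------------------------------------------------------------------

def read_pwm(path: str | Path, name: str | None = None, pseudocount: float = 0.001) -> PWM:
    """Read a whitespace-delimited 4-row (A, C, G, T) probability matrix.

    A leading ``>name`` line (JASPAR-like) is honoured; row labels such
    as ``A [ ... ]`` are stripped.
    """
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].split()[0]
                continue
            for ch in "ACGT[]":
                line = line.replace(ch + " ", " ") if ch in "ACGT" else line.replace(ch, " ")
            rows.append([float(x) for x in line.split()])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 rows (A,C,G,T), got {len(rows)}")
    matrix = np.array(rows).T  # rows were per-base, we store length x 4
    if name is None:
        name = header or Path(path).stem
    return PWM(name, matrix, pseudocount)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i in range(4):
            fh.write(" ".join(f"{v:.6f}" for v in pwm.matrix[:, i]) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every window and a validity mask (no N in window)."""
    L = lo.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows != 4).all(axis=1)
    lo_ext = np.vstack([lo.T, np.zeros(L)])  # row 4 absorbs N codes harmlessly
    scores = lo_ext[windows, np.arange(L)].sum(axis=1)
    return scores, valid


def pwm_scan(
    sequence: str,
    pwm: PWM,
    score_threshold: float,
    background: np.ndarray | None = None,
) -> list[MotifOccurrence]:
    """Scan both strands for windows scoring >= ``score_threshold`` bits.

    Scores are log2 odds against the background (uniform by default).
    Windows containing N are skipped.  Minus-strand hits are reported at
    their forward-strand window start.  A motif longer than the sequence
    yields an empty result.
    """
    if pwm.length > len(sequence):
        return []
    codes = _encode(sequence)
    hits: list[MotifOccurrence] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores, valid = _scan_one_strand(codes, mat.log_odds(background))
        for pos in np.flatnonzero(valid & (scores >= score_threshold)):
            hits.append(MotifOccurrence(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    pwm_library: Sequence[PWM],
    score_threshold: float | None = None,
    threshold_fraction: float = 0.8,
) -> pd.DataFrame:
    """Per-motif enrichment of target vs background sequences.

    A sequence "contains" a motif when it has >= 1 hit on either strand.
    Per motif, a one-tailed hypergeometric test compares the number of
    hit-containing targets against the pooled sequence set, and BH
    correction is applied across motifs.  When ``score_threshold`` is
    None each motif uses ``threshold_fraction`` of its maximum
    achievable log-odds score.
    """
    if len(background_seqs) == 0:
        raise ValueError("empty background sequence set")
    if len(target_seqs) == 0:
        raise ValueError("empty target sequence set")
    rows = []
    for pwm in pwm_library:
        thr = (
            score_threshold
            if score_threshold is not None
            else threshold_fraction * pwm.max_score()
        )
        t_hit = sum(1 for s in target_seqs if pwm_scan(s, pwm, thr))
        b_hit = sum(1 for s in background_seqs if pwm_scan(s, pwm, thr))
        n_t, n_b = len(target_seqs), len(background_seqs)
        # P(X >= t_hit) drawing n_t sequences from the pool of hits
        p = float(stats.hypergeom.sf(t_hit - 1, n_t + n_b, t_hit + b_hit, n_t))
        rows.append((pwm.name, n_t, t_hit, n_b, b_hit, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=[
            "motif", "n_target", "target_hits", "n_background", "background_hits",
            "p_value",
        ],
    )
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p_value", "motif"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# footprint profiles
# ---------------------------------------------------------------------------

def aggregate_footprint(
    cut_index: Mapping[str, np.ndarray],
    sites: Sequence[MotifSite],
    window: int = 100,
    flank: int = 20,
    tf_name: str = "TF",
) -> FootprintProfile:
    """Aggregate strand-oriented cut counts in +/-``window`` of motif centres.

    ``cut_index`` maps chromosome -> sorted cut positions (see
    :func:`chondroatac.signal_peaks.cut_site_index`).  Minus-strand site
    profiles are reversed before summing.  The centre region is the
    motif span around the centre; the flanks are the outermost ``flank``
    bp on each side of the window.
    """
    if len(sites) == 0:
        raise ValueError("need at least one motif site")
    width = 2 * window + 1
    profile = np.zeros(width, dtype=np.int64)
    for site in sites:
        pos = cut_index.get(site.chrom)
        if pos is None:
            continue
        c = site.center
        lo = np.searchsorted(pos, c - window)
        hi = np.searchsorted(pos, c + window + 1)
        offsets = pos[lo:hi] - (c - window)
        if site.strand == "-":
            offsets = width - 1 - offsets
        np.add.at(profile, offsets, 1)

    motif_len = int(np.median([s.length for s in sites]))
    half = motif_len // 2
    center = profile[window - half : window - half + motif_len]
    flanks = np.concatenate([profile[:flank], profile[-flank:]])
    center_mean = max(float(center.mean()), 1.0)
    depth = float(flanks.mean()) / center_mean
    return FootprintProfile(
        tf_name=tf_name,
        window=window,
        counts=profile,
        n_sites=len(sites),
        motif_length=motif_len,
        depth_score=depth,
    )


def classify_active(
    profile: FootprintProfile,
    min_depth: float = 1.5,
    min_sites: int = 50,
    smooth_window: int = 5,
) -> str:
    """Classify a TF as ``active``, ``inactive`` or ``indeterminate``.

    ``indeterminate`` when too few sites support the profile.  ``active``
    requires both a deep enough footprint (depth_score >= min_depth) and
    a well-formed one: the global minimum of the ``smooth_window``-bp
    moving-average profile must fall within the motif span — a dip
    elsewhere means the curve is disordered rather than protected.
    """
    if profile.n_sites < min_sites:
        return "indeterminate"
    if profile.depth_score < min_depth:
        return "inactive"
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(profile.counts.astype(float), kernel, mode="valid")
    trim = (smooth_window - 1) // 2
    argmin = int(np.argmin(smoothed)) + trim  # offset in the full profile
    half = profile.motif_length // 2
    center_lo = profile.window - half
    center_hi = center_lo + profile.motif_length
    if center_lo <= argmin < center_hi:
        return "active"
    return "inactive"


def crosscheck_expression(
    tf_calls: Mapping[str, str],
    tpm: pd.DataFrame,
    tf_gene_map: Mapping[str, str],
    tpm_threshold: float = 2.0,
) -> pd.DataFrame:
    """Join footprint calls with RNA-seq expression of the encoding gene.

    A TF is ``expressed`` when its gene's mean TPM strictly exceeds the
    threshold; an active TF with an expressed gene (or inactive with a
    non-expressed one) is ``concordant``.  TFs absent from the map are
    flagged ``unmapped`` rather than dropped.
    """
    mean_tpm = tpm.mean(axis=1)
    rows = []
    for tf, call in sorted(tf_calls.items()):
        gene = tf_gene_map.get(tf)
        if gene is None or gene not in mean_tpm.index:
            rows.append((tf, call, None, np.nan, None, "unmapped"))
            continue
        expr = float(mean_tpm.loc[gene])
        expressed = expr > tpm_threshold
        if call == "indeterminate":
            status = "indeterminate"
        elif (call == "active") == expressed:
            status = "concordant"
        else:
            status = "discordant"
        rows.append((tf, call, gene, expr, expressed, status))
    return pd.DataFrame(
        rows,
        columns=["tf", "footprint_call", "gene", "mean_tpm", "expressed", "status"],
    )
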