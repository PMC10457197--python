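"""PWM scanning and motif enrichment of target vs background sequences.

A position weight matrix scores every window of a sequence (both strands)
by the log-odds sum log2(p_j(b) / q(b)); a window is a hit when its score
reaches ``score_fraction`` of the maximal achievable score, and a sequence
is motif-positive when it has at least one hit — the sequence-level
"% of target sequences with motif" convention. Enrichment of presence in
targets over background uses the same exact Fisher test as the
feature-enrichment module.

Sequences are plain A/C/G/T/N strings or Biopython SeqRecords; N scores as
background (contributes 0 to the log-odds sum). Synthetic test sequences
(i.i.d. bases at a configurable GC) and mononucleotide shuffles live here
so FASTA concerns stay local to this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .diffexpr import bh_adjust
from .enrichment import hypergeom_tails

__all__ = [
    "Pwm",
    "read_pwms",
    "write_pwms",
    "scan_sequences",
    "motif_enrichment",
    "random_sequences",
    "mononucleotide_shuffle",
    "sample_site",
    "read_fasta",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)} | {"N": 4}
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Position probability matrix with pseudocount and background."""

    motif_id: str
    probs: np.ndarray  # length x 4, rows sum to 1
    pseudocount: float = 0.01
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ConfigurationError("PWM must be length x 4")
        if len(self.probs) < 4:
            raise ConfigurationError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError(
                f"PWM {self.motif_id}: position probabilities must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L lookup (A, C, G, T, N) of log2 odds; N scores 0."""
        p = (self.probs + self.pseudocount) / (1.0 + 4 * self.pseudocount)
        lo = np.log2(p / self.background)
        return np.vstack([lo.T, np.zeros(len(self.probs))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str,
                       major_prob: float = 0.9) -> "Pwm":
        minor = (1.0 - major_prob) / 3.0
        probs = np.full((len(consensus), 4), minor)
        for i, b in enumerate(consensus.upper()):
            probs[i, _CODE[b]] = major_prob
        return cls(motif_id=motif_id, probs=probs)


def read_pwms(path: str | Path) -> list[Pwm]:
    """Read the simple PWM text format: ``>id`` header, one row of four
    probabilities per position."""
    pwms: list[Pwm] = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(Pwm(name, np.array(rows)))
                name, rows = line[1:].split()[0], []
            else:
                rows.append([float(x) for x in line.split()])
    if name is not None:
        pwms.append(Pwm(name, np.array(rows)))
    return pwms


def write_pwms(pwms: list[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    length = lo.shape[1]
    if len(codes) < length:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, length)
    return lo[win, np.arange(length)].sum(axis=1)


def scan_sequences(
    seqs: dict[str, str],
    pwm: Pwm,
    score_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scan sequences with one PWM on both strands.

    Returns (hits, presence): hits has one row per window with score >=
    score_fraction x max achievable score (sequence id, 0-based offset on
    the forward sequence, strand, score); presence flags each sequence with
    >= 1 hit. Sequences shorter than the motif get no hits and are flagged
    in ``presence`` as False.
    """
    if not 0 < score_fraction <= 1:
        raise ConfigurationError("score_fraction must be in (0, 1]")
    lo = pwm.log_odds
    threshold = score_fraction * pwm.max_score
    rows = []
    presence = {}
    for sid, seq in seqs.items():
        found = False
        codes_f = _encode(seq)
        rc = seq.translate(_COMP)[::-1]
        for strand, codes in (("+", codes_f), ("-", _encode(rc))):
            scores = _window_scores(codes, lo)
            for off in np.flatnonzero(scores >= threshold):
                pos = int(off) if strand == "+" else len(seq) - int(off) - len(pwm)
                rows.append((sid, pos, strand, float(scores[off])))
                found = True
        presence[sid] = found
    hits = pd.DataFrame(rows, columns=["sequence", "start", "strand", "score"])
    return hits, pd.Series(presence, name=pwm.motif_id)


def motif_enrichment(
    targets: dict[str, str],
    background: dict[str, str] | None,
    pwms: list[Pwm],
    score_fraction: float = 0.8,
    shuffle_seed: int = 0,
) -> pd.DataFrame:
    """Per-motif sequence-presence enrichment of targets over background.

    Counts motif-positive sequences in each set, tests the 2x2 with a
    one-sided (greater) Fisher exact test, BH-adjusts across motifs, and
    sorts by p. With no background given, a seeded mononucleotide shuffle
    of the targets serves as background (preserves base composition,
    destroys motifs).
    """
    if not targets:
        raise ConfigurationError("targets must be non-empty")
    if background is None:
        rng = np.random.Generator(np.random.PCG64(shuffle_seed))
        background = {f"shuf_{sid}": mononucleotide_shuffle(seq, rng)
                      for sid, seq in targets.items()}
    if not background:
        raise ConfigurationError("background must be non-empty")
    rows = []
    for pwm in pwms:
        _, pres_t = scan_sequences(targets, pwm, score_fraction)
        _, pres_b = scan_sequences(background, pwm, score_fraction)
        k_t, k_b = int(pres_t.sum()), int(pres_b.sum())
        n_t, n_b = len(targets), len(background)
        p_greater, _ = hypergeom_tails(k_t, k_t + k_b, n_t, n_t + n_b)
        rows.append((pwm.motif_id, k_t, 100.0 * k_t / n_t,
                     k_b, 100.0 * k_b / n_b, p_greater))
    out = pd.DataFrame(rows, columns=[
        "motif", "targets_with_motif", "pct_targets_with_motif",
        "background_with_motif", "pct_background_with_motif", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "motif"], kind="mergesort").reset_index(drop=True)


def random_sequences(n: int, length: int, rng: np.random.Generator,
                     gc: float = 0.5, prefix: str = "seq") -> dict[str, str]:
    """I.i.d. random sequences at the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for i in range(n):
        codes = rng.choice(4, size=length, p=p)
        out[f"{prefix}{i:04d}"] = "".join(_BASES[c] for c in codes)
    return out


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    """Draw one site from the PWM's position probabilities."""
    return "".join(_BASES[rng.choice(4, p=row / row.sum())]
                   for row in pwm.probs)


def plant_motif(seqs: dict[str, str], pwm: Pwm, fraction: float,
                rng: np.random.Generator, exact: bool = True) -> dict[str, str]:
    """Plant one motif site at a random position in a fraction of sequences.

    With ``exact`` (default) the consensus site is implanted — a guaranteed
    occurrence at any sensible score threshold; otherwise sites are sampled
    from the PWM probabilities, so sharp thresholds may miss degenerate
    draws. Returns a new dict."""
    out = {}
    ids = list(seqs)
    chosen = set(rng.choice(len(ids), size=int(round(fraction * len(ids))),
                            replace=False))
    for i, sid in enumerate(ids):
        seq = seqs[sid]
        if i in chosen and len(seq) >= len(pwm):
            site = pwm.consensus if exact else sample_site(pwm, rng)
            pos = int(rng.integers(0, len(seq) - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        out[sid] = seq
    return out
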