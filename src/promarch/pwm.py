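"""Position weight matrices and the default core-promoter motif library.

The default motifs are idealized consensus-derived models for the classic
Drosophila core-promoter elements (TATA-box, INR, DPE, TCT, DRE, Ohler1/6/7,
MTE), built from IUPAC consensus strings: allowed bases at each position
share the bulk of the probability mass and every disallowed base keeps a
small pseudocount. They are meant to give the expected positional
specificity, not to reproduce any published matrix — swap in trained
matrices via :func:`read_pwms` for real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass
class PWM:
    """An L x 4 matrix of per-position base probabilities (columns A,C,G,T)."""

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be an L x 4 matrix")
        if self.length < 2:
            raise ValueError("PWM length must be >= 2")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("PWM probabilities must be positive (apply a pseudocount)")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1) > 1e-9:
            raise ValueError("background must be a positive probability vector")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str,
                       mismatch_p: float = 0.03) -> "PWM":
        """Build a PWM from an IUPAC consensus string.

        At each position the bases allowed by the IUPAC code split
        ``1 - mismatch_p * n_disallowed`` evenly; each disallowed base gets
        ``mismatch_p``.
        """
        rows = []
        for ch in consensus.upper():
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r}")
            allowed = IUPAC[ch]
            row = np.full(4, mismatch_p)
            share = (1.0 - mismatch_p * (4 - len(allowed))) / len(allowed)
            for b in allowed:
                row[BASE_INDEX[b]] = share
            rows.append(row)
        return cls(motif_id, np.array(rows))

    def consensus(self) -> str:
        """One maximal-probability base per position (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def anti_consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmin(axis=1))


# ---------------------------------------------------------------------------
# default motif library

# Consensus strings are idealized; embed offsets and search windows are
# motif-start positions relative to the TSS (downstream positive).
_DEFAULT_MOTIFS: dict[str, tuple[str, tuple[int, int]]] = {
    "TATA":   ("STATAAAAR",    (-36, -26)),
    "INR":    ("TCAGTY",       (-5, 5)),
    "DPE":    ("RGWYGT",       (23, 33)),
    "TCT":    ("TCTTTC",       (-5, 5)),
    "DRE":    ("TATCGATA",     (-65, -55)),
    "Ohler1": ("GGTCACACTG",   (-50, -40)),
    "Ohler6": ("KTYRGTATWTTT", (-30, -20)),
    "Ohler7": ("CAKCNCTR",     (-40, -10)),
    "MTE":    ("CSARCSSAACGS", (18, 30)),
}

#: Percent-of-optimum thresholds defining binary motif presence.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "TATA": 90.0, "INR": 95.0, "DPE": 98.0, "TCT": 95.0,
    "Ohler1": 95.0, "Ohler6": 97.0, "Ohler7": 95.0, "DRE": 98.0,
}

DEVELOPMENTAL_MOTIFS = ("TATA", "INR", "DPE", "MTE")
HOUSEKEEPING_MOTIFS = ("TCT", "DRE", "Ohler1", "Ohler6", "Ohler7")


def default_pwms() -> dict[str, PWM]:
    return {name: PWM.from_consensus(name, cons)
            for name, (cons, _win) in _DEFAULT_MOTIFS.items()}


def default_windows() -> dict[str, tuple[int, int]]:
    return {name: win for name, (_cons, win) in _DEFAULT_MOTIFS.items()}


def default_embed_offsets() -> dict[str, int]:
    """Default TSS-relative motif-start offsets used when embedding motifs."""
    return {"TATA": -31, "INR": 0, "DPE": 28, "TCT": 0,
            "DRE": -60, "Ohler1": -45, "Ohler6": -25}


# ---------------------------------------------------------------------------
# text format: one header line per motif, one row per position


def write_pwms(pwms: dict[str, PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms.values():
            fh.write(f">{pwm.motif_id}\n")
            fh.write("#background "
                     + " ".join(repr(float(v)) for v in pwm.background) + "\n")
            for row in pwm.probs:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_pwms(path) -> dict[str, PWM]:
    pwms: dict[str, PWM] = {}
    name, rows, background = None, [], None

    def flush():
        if name is not None:
            kwargs = {} if background is None else {"background": np.array(background)}
            pwms[name] = PWM(name, np.array(rows), **kwargs)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows, background = line[1:].strip(), [], None
            elif line.startswith("#background"):
                background = [float(v) for v in line.split()[1:]]
            else:
                rows.append([float(v) for v in line.split()])
    flush()
    return pwms
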