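"""Sequence-derived per-residue state features for disorder prediction.

Four tracks are combined into one L x 242 matrix per protein:

* evolutionary profile: a PSI-BLAST position-specific scoring matrix (PSSM),
  normalized to [0, 1] and windowed over the 11 residues centered on the
  target (20 x 11 = 220 columns);
* residue composition: frequencies of the 20 standard amino acids within the
  same 11-residue window (k = 1 "kmer" features, 20 columns);
* predicted secondary structure (PSIPRED three-class), encoded as one scalar;
* predicted relative solvent accessibility (SABLE-style), one scalar in [0, 1].

Windows are clipped or padded at the chain termini: PSSM windows pad with the
normalized-zero row (all 0.5), composition windows use the clipped window and
its true residue count as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AA_ORDER_PSIBLAST",
    "AA_ORDER_KMER",
    "RawPSSM",
    "SecondaryStructureTrack",
    "RSATrack",
    "StateFeatureMatrix",
    "parse_pssm_ascii",
    "normalize_pssm",
    "pssm_window_features",
    "kmer_window_features",
    "parse_psipred_ss2",
    "parse_sable",
    "encode_secondary_structure",
    "assemble_state_features",
]

#: column order of PSI-BLAST ASCII PSSM output
AA_ORDER_PSIBLAST = "ARNDCQEGHILKMFPSTWYV"
#: alphabetical order used for the composition (kmer) block
AA_ORDER_KMER = "ACDEFGHIKLMNPQRSTVWY"

#: default scalar code for the three secondary-structure classes
SS_CODES = {"C": 0.0, "H": 0.5, "E": 1.0}

_STANDARD_AA = set(AA_ORDER_KMER)


class FeatureParseError(ValueError):
    """Raised when an external feature file cannot be parsed or aligned."""


@dataclass
class RawPSSM:
    """PSI-BLAST log-odds profile: residue string plus an L x 20 score matrix."""

    sequence_id: str
    residues: str
    scores: np.ndarray  # (L, 20), PSI-BLAST column order
    aa_order: str = AA_ORDER_PSIBLAST

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FeatureParseError(f"{self.sequence_id}: PSSM must have exactly 20 score columns")
        if len(self.residues) != self.scores.shape[0]:
            raise FeatureParseError(f"{self.sequence_id}: PSSM rows != residue count")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class SecondaryStructureTrack:
    """Per-residue three-class secondary structure (H helix, E strand, C coil)."""

    classes: str  # string over {H, E, C}
    residues: str | None = None
    confidences: np.ndarray | None = None  # (L, 3) P(C), P(H), P(E)

    def __post_init__(self) -> None:
        bad = set(self.classes) - {"H", "E", "C"}
        if bad:
            raise FeatureParseError(f"unknown secondary-structure classes {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.classes)


@dataclass
class RSATrack:
    """Per-residue relative solvent accessibility stored as a fraction in [0, 1]."""

    values: np.ndarray
    residues: str | None = None
    detected_percent_scale: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise FeatureParseError("RSA values must be finite")
        if self.values.min() < 0 or self.values.max() > 1:
            raise FeatureParseError("RSA fractions must lie in [0, 1]")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class StateFeatureMatrix:
    """Assembled L x F matrix plus the column-block layout that produced it."""

    matrix: np.ndarray
    blocks: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> [start, stop)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _check_residues(kind: str, got: str, expected: str | None) -> None:
    if expected is None:
        return
    if len(got) != len(expected):
        raise FeatureParseError(
            f"{kind}: length {len(got)} does not match sequence length {len(expected)}"
        )
    for i, (a, b) in enumerate(zip(got, expected), start=1):
        if a != b and a != "X" and b != "X":
            raise FeatureParseError(f"{kind}: residue mismatch at position {i}: {a!r} != {b!r}")


def parse_pssm_ascii(path, expected_sequence: str | None = None) -> RawPSSM:
    """Read a PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect).

    Only the first 20 numeric columns (the log-odds scores) are kept; the
    percentage columns and per-row statistics are ignored.  Residue letters
    are retained and, when ``expected_sequence`` is given, cross-checked.
    """
    aa_order = AA_ORDER_PSIBLAST
    residues: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
            aa_order = "".join(tokens[:20])
            continue
        if not tokens[0].lstrip("-").isdigit():
            continue  # header / footer prose
        if len(tokens) < 2 or not tokens[1].isalpha():
            continue
        idx = int(tokens[0])
        if idx != len(rows) + 1:
            raise FeatureParseError(f"{path}: line {lineno}: expected row {len(rows) + 1}, got {idx}")
        values = tokens[2:22]
        if len(values) < 20:
            raise FeatureParseError(
                f"{path}: line {lineno}: expected 20 score columns, found {len(values)}"
            )
        try:
            rows.append([float(v) for v in values])
        except ValueError:
            raise FeatureParseError(f"{path}: line {lineno}: non-numeric score column") from None
        residues.append(tokens[1])
    if not rows:
        raise FeatureParseError(f"{path}: no PSSM rows found")
    pssm = RawPSSM(str(path), "".join(residues), np.array(rows), aa_order=aa_order)
    _check_residues(f"{path} (PSSM)", pssm.residues, expected_sequence)
    return pssm


def normalize_pssm(raw: RawPSSM | np.ndarray) -> np.ndarray:
    """Squash log-odds scores to [0, 1]: 0 below -5, 1 above +5, 0.5 + 0.1 x between."""
    scores = raw.scores if isinstance(raw, RawPSSM) else np.asarray(raw, dtype=float)
    return np.clip(0.5 + 0.1 * scores, 0.0, 1.0)


def pssm_window_features(norm: np.ndarray, position: int, window: int = 11) -> np.ndarray:
    """Concatenated normalized profile rows of the window centered on ``position`` (1-based).

    Out-of-range window slots contribute the normalized-zero row (all 0.5),
    so the output always has length ``20 * window`` (220 by default).
    """
    if window % 2 == 0 or window < 1:
        raise FeatureParseError(f"window must be a positive odd integer, got {window}")
    norm = np.asarray(norm, dtype=float)
    L = norm.shape[0]
    if not 1 <= position <= L:
        raise FeatureParseError(f"position {position} out of range 1..{L}")
    half = window // 2
    out = np.full((window, norm.shape[1]), 0.5)
    for w, p in enumerate(range(position - half, position + half + 1)):
        if 1 <= p <= L:
            out[w] = norm[p - 1]
    return out.ravel()


def kmer_window_features(
    sequence: str, position: int, window: int = 11, k: int = 1
) -> np.ndarray:
    """Amino-acid frequencies in the clipped window around ``position`` (1-based).

    The denominator is the number of standard residues actually inside the
    clipped window, so the 20 entries sum to 1 whenever the window contains
    only standard residues.  Non-standard letters (B, J, O, U, X, Z) are
    excluded from both numerator and denominator.
    """
    if k != 1:
        raise FeatureParseError("only k = 1 composition features are supported")
    if not sequence:
        raise FeatureParseError("empty sequence")
    L = len(sequence)
    if not 1 <= position <= L:
        raise FeatureParseError(f"position {position} out of range 1..{L}")
    half = window // 2
    lo = max(1, position - half)
    hi = min(L, position + half)
    counts = np.zeros(20)
    n = 0
    for p in range(lo, hi + 1):
        aa = sequence[p - 1].upper()
        if aa in _STANDARD_AA:
            counts[AA_ORDER_KMER.index(aa)] += 1
            n += 1
    if n:
        counts /= n
    return counts


def parse_psipred_ss2(path, expected_sequence: str | None = None) -> SecondaryStructureTrack:
    """Read a PSIPRED ``.ss2`` file: index, residue, class, then C/H/E confidences."""
    residues: list[str] = []
    classes: list[str] = []
    confs: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if not tokens[0].isdigit():
                continue
            if len(tokens) < 3:
                raise FeatureParseError(f"{path}: line {lineno}: malformed .ss2 row")
            idx = int(tokens[0])
            if idx != len(classes) + 1:
                raise FeatureParseError(
                    f"{path}: line {lineno}: expected row {len(classes) + 1}, got {idx}"
                )
            residues.append(tokens[1])
            classes.append(tokens[2])
            if len(tokens) >= 6:
                confs.append([float(t) for t in tokens[3:6]])
    if not classes:
        raise FeatureParseError(f"{path}: no .ss2 rows found")
    res = "".join(residues)
    _check_residues(f"{path} (.ss2)", res, expected_sequence)
    track = SecondaryStructureTrack(
        "".join(classes),
        residues=res,
        confidences=np.array(confs) if len(confs) == len(classes) else None,
    )
    return track


def parse_sable(path, expected_sequence: str | None = None) -> RSATrack:
    """Read a SABLE-style per-residue relative solvent accessibility table.

    Accepts whitespace-separated rows of ``index residue value``, ``residue
    value`` or bare ``value``; the unit (fraction vs percent) is detected
    automatically — any value above 1.5 marks the whole file as percent.
    """
    residues: list[str] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            try:
                value = float(tokens[-1])
            except ValueError:
                continue  # header prose
            if len(tokens) >= 2 and tokens[-2].isalpha() and len(tokens[-2]) == 1:
                residues.append(tokens[-2])
            values.append(value)
    if not values:
        raise FeatureParseError(f"{path}: no RSA rows found")
    arr = np.array(values, dtype=float)
    percent = bool(np.any(arr > 1.5))
    if percent:
        arr = arr / 100.0
    res = "".join(residues) if len(residues) == len(values) else None
    if res is not None:
        _check_residues(f"{path} (RSA)", res, expected_sequence)
    elif expected_sequence is not None and len(values) != len(expected_sequence):
        raise FeatureParseError(
            f"{path}: RSA length {len(values)} does not match sequence length "
            f"{len(expected_sequence)}"
        )
    return RSATrack(np.clip(arr, 0.0, 1.0), residues=res, detected_percent_scale=percent)


def encode_secondary_structure(
    track_or_class: SecondaryStructureTrack | str,
    position: int | None = None,
    codes: dict[str, float] = SS_CODES,
) -> float | np.ndarray:
    """Scalar code of a secondary-structure class (default C=0, H=0.5, E=1).

    With a track and a 1-based ``position`` returns that residue's code; with
    a track alone returns the whole coded vector.
    """
    if isinstance(track_or_class, SecondaryStructureTrack):
        if position is None:
            return np.array([codes[c] for c in track_or_class.classes])
        cls = track_or_class.classes[position - 1]
    else:
        cls = track_or_class
    if cls not in codes:
        raise FeatureParseError(f"unknown secondary-structure class {cls!r}")
    return codes[cls]


def assemble_state_features(
    sequence: str,
    norm_pssm: np.ndarray,
    ss_track: SecondaryStructureTrack | None = None,
    rsa_track: RSATrack | None = None,
    window: int = 11,
    ss_codes: dict[str, float] = SS_CODES,
) -> StateFeatureMatrix:
    """Stack all per-residue feature blocks into one L x F matrix.

    Row i is ``[pssm_window(i) | composition_window(i) | ss_code(i) | rsa(i)]``;
    with every track present F = 220 + 20 + 1 + 1 = 242.  Omitted tracks
    simply drop their block (recorded in the block layout).
    """
    L = len(sequence)
    norm_pssm = np.asarray(norm_pssm, dtype=float)
    if norm_pssm.shape[0] != L:
        raise FeatureParseError(f"PSSM rows {norm_pssm.shape[0]} != sequence length {L}")
    if ss_track is not None and ss_track.length != L:
        raise FeatureParseError(f"SS track length {ss_track.length} != sequence length {L}")
    if rsa_track is not None and rsa_track.length != L:
        raise FeatureParseError(f"RSA track length {rsa_track.length} != sequence length {L}")

    cols: list[np.ndarray] = []
    blocks: dict[str, tuple[int, int]] = {}
    pssm_block = np.stack([pssm_window_features(norm_pssm, i, window) for i in range(1, L + 1)])
    blocks["pssm_window"] = (0, pssm_block.shape[1])
    cols.append(pssm_block)
    offset = pssm_block.shape[1]

    kmer_block = np.stack([kmer_window_features(sequence, i, window) for i in range(1, L + 1)])
    blocks["kmer"] = (offset, offset + 20)
    cols.append(kmer_block)
    offset += 20

    if ss_track is not None:
        ss_col = np.array([[encode_secondary_structure(c, codes=ss_codes)]
                           for c in ss_track.classes])
        blocks["secondary_structure"] = (offset, offset + 1)
        cols.append(ss_col)
        offset += 1

    if rsa_track is not None:
        blocks["rsa"] = (offset, offset + 1)
        cols.append(rsa_track.values[:, None])
        offset += 1

    matrix = np.hstack(cols)
    assert matrix.shape == (L, offset)
    return StateFeatureMatrix(matrix, blocks)


def write_feature_matrix(path, sfm: StateFeatureMatrix, sequence_id: str,
                         provenance: str = "") -> None:
    """Cache an assembled feature matrix as TSV with a self-describing header."""
    import json as _json

    with open(path, "w") as fh:
        fh.write("# disocrf feature matrix v1\n")
        fh.write(f"# id: {sequence_id}\n")
        fh.write(f"# shape: {sfm.matrix.shape[0]} {sfm.matrix.shape[1]}\n")
        fh.write(f"# blocks: {_json.dumps(sfm.blocks)}\n")
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        np.savetxt(fh, sfm.matrix, fmt="%.8g", delimiter="\t")


def read_feature_matrix(path) -> tuple[str, StateFeatureMatrix]:
    """Read a cached feature matrix; returns (sequence_id, matrix-with-blocks)."""
    import json as _json

    sequence_id = str(path)
    blocks: dict[str, tuple[int, int]] = {}
    shape = None
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line[1:].strip()
            if body.startswith("id:"):
                sequence_id = body[3:].strip()
            elif body.startswith("shape:"):
                shape = tuple(int(t) for t in body[6:].split())
            elif body.startswith("blocks:"):
                blocks = {k: tuple(v) for k, v in _json.loads(body[7:]).items()}
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if shape is not None and tuple(matrix.shape) != shape:
        raise FeatureParseError(f"{path}: matrix shape {matrix.shape} != declared {shape}")
    return sequence_id, StateFeatureMatrix(matrix, blocks)
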