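"""Synthetic labelled proteins with state-conditioned feature tracks.

Order/disorder labels follow a two-state first-order Markov chain started
from its stationary distribution, so disordered residues come in runs, as
they do in real chains.  Conditional on the label, the four feature tracks
are emitted independently per position:

* raw PSSM scores: Gaussian with a state-dependent mean shift, clipped to
  [-10, 10].  The per-column shift is ``delta * noise_sd / (2 * sqrt(20))``
  so that the whole 20-column profile carries a Mahalanobis separation of
  ``delta`` between the states;
* residue identity: drawn from a disorder- or order-enriched composition
  (disorder favors P/E/S/Q/K/G/A/R, order favors W/F/Y/I/L/V/C/M), mixed
  toward the common background with strength ``min(delta, 3) / 3``;
* secondary structure: disordered positions emit coil with high probability,
  ordered positions a helix/strand-rich mix, with the same mixing strength;
* relative solvent accessibility: Gaussian, disordered mean higher by
  ``delta * rsa_sd``, clipped to [0, 1].

At ``delta = 0`` every track's distribution is identical across states; the
separation grows monotonically with ``delta``.  The generator writes the same
FASTA / ASCII-PSSM / .ss2 / RSA / interval files the real pipeline reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import features as feat
from .crf import LabeledSequence, ObservationSequence
from .evaluation import labels_to_intervals, write_interval_table

__all__ = [
    "SyntheticConfig",
    "generate_label_chain",
    "emit_feature_tracks",
    "generate_dataset",
    "write_fixture_dir",
]

_DISORDER_AA = "PESQKGAR"
_ORDER_AA = "WFYILVCM"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    ``stay_o`` / ``stay_d`` are the Markov self-transition probabilities
    (persistence 0.95 gives mean segments of 20 residues, the scale of
    typical crystallographic disordered regions); their ratio sets the
    stationary disorder fraction.  ``delta`` is the per-track emission
    separation in units of the emission SD.
    """

    n_proteins: int = 50
    min_length: int = 60
    max_length: int = 200
    stay_o: float = 0.95
    stay_d: float = 0.95
    delta: float = 3.0
    noise_sd: float = 1.0
    rsa_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.stay_o, self.stay_d):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("persistence probabilities must lie in [0, 1]")
        if self.delta < 0:
            raise SimulationError("delta must be >= 0")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise SimulationError("invalid length range")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Rows (O, D) of the label chain's transition probabilities."""
        return np.array(
            [[self.stay_o, 1.0 - self.stay_o], [1.0 - self.stay_d, self.stay_d]]
        )

    @property
    def stationary_disorder_fraction(self) -> float:
        leave_o = 1.0 - self.stay_o
        leave_d = 1.0 - self.stay_d
        if leave_o + leave_d == 0:
            return 0.5  # both states absorbing; start state is a coin flip
        return leave_o / (leave_o + leave_d)


def generate_label_chain(config: SyntheticConfig, length: int, rng: np.random.Generator) -> str:
    """Sample an O/D chain of the given length from the stationary Markov chain."""
    P = config.transition_matrix
    if not np.allclose(P.sum(axis=1), 1.0) or np.any(P < 0):
        raise SimulationError("transition matrix rows must be probability vectors")
    pi_d = config.stationary_disorder_fraction
    states = np.empty(length, dtype=np.intp)
    states[0] = rng.random() < pi_d
    for i in range(1, length):
        states[i] = rng.random() < P[states[i - 1], 1]
    return "".join("D" if s else "O" for s in states)


def _mixing(delta: float) -> float:
    return min(delta, 3.0) / 3.0


def _aa_distributions(delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Residue compositions for (O, D): background mixed with enriched sets."""
    base = np.full(20, 0.05)
    dis = np.full(20, 0.28 / 12)
    for aa in _DISORDER_AA:
        dis[feat.AA_ORDER_KMER.index(aa)] = 0.09
    orde = np.full(20, 0.28 / 12)
    for aa in _ORDER_AA:
        orde[feat.AA_ORDER_KMER.index(aa)] = 0.09
    f = _mixing(delta)
    return (1 - f) * base + f * orde, (1 - f) * base + f * dis


def _ss_distributions(delta: float) -> np.ndarray:
    """(2, 3) probabilities over (C, H, E) for states (O, D)."""
    base = np.array([0.45, 0.35, 0.20])
    target_o = np.array([0.25, 0.45, 0.30])
    target_d = np.array([0.90, 0.05, 0.05])
    f = _mixing(delta)
    return np.stack([(1 - f) * base + f * target_o, (1 - f) * base + f * target_d])


def emit_feature_tracks(
    labels: str, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[feat.RawPSSM, str, feat.SecondaryStructureTrack, feat.RSATrack]:
    """Sample the four feature tracks conditional on a label chain."""
    L = len(labels)
    state = np.array([c == "D" for c in labels], dtype=np.intp)

    shift = config.delta * config.noise_sd / (2.0 * np.sqrt(20.0))
    means = np.where(state[:, None] == 1, shift, -shift)
    scores = np.clip(rng.normal(means, config.noise_sd, size=(L, 20)), -10.0, 10.0)

    p_o, p_d = _aa_distributions(config.delta)
    seq_chars = [
        feat.AA_ORDER_KMER[rng.choice(20, p=p_d if s else p_o)] for s in state
    ]
    sequence = "".join(seq_chars)

    ss_p = _ss_distributions(config.delta)
    ss_classes = "".join("CHE"[rng.choice(3, p=ss_p[s])] for s in state)

    rsa_mean = np.where(state == 1, 0.35 + config.delta * config.rsa_sd, 0.35)
    rsa = np.clip(rng.normal(rsa_mean, config.rsa_sd), 0.0, 1.0)

    pssm = feat.RawPSSM("synthetic", sequence, scores)
    ss_track = feat.SecondaryStructureTrack(ss_classes, residues=sequence)
    rsa_track = feat.RSATrack(rsa, residues=sequence)
    return pssm, sequence, ss_track, rsa_track


def _featurize(sequence: str, pssm: feat.RawPSSM,
               ss: feat.SecondaryStructureTrack, rsa: feat.RSATrack) -> np.ndarray:
    norm = feat.normalize_pssm(pssm)
    return feat.assemble_state_features(sequence, norm, ss, rsa).matrix


def generate_dataset(
    config: SyntheticConfig, id_prefix: str = "syn", return_tracks: bool = False
):
    """Fully featurized labelled proteins plus a manifest recording the conditions."""
    rng = np.random.default_rng(config.seed)
    data: list[LabeledSequence] = []
    raw_tracks = []
    for i in range(config.n_proteins):
        L = int(rng.integers(config.min_length, config.max_length + 1))
        labels = generate_label_chain(config, L, rng)
        pssm, sequence, ss, rsa = emit_feature_tracks(labels, config, rng)
        obs = ObservationSequence(f"{id_prefix}{i:04d}", _featurize(sequence, pssm, ss, rsa))
        data.append(LabeledSequence(obs, labels))
        raw_tracks.append((pssm, sequence, ss, rsa))
    manifest = {
        "generator": "disocrf.simulate",
        "config": asdict(config),
        "n_proteins": len(data),
        "n_residues": int(sum(s.observation.length for s in data)),
        "n_disordered": int(sum(s.labels.count("D") for s in data)),
        "ids": [s.observation.sequence_id for s in data],
    }
    if return_tracks:
        return data, manifest, raw_tracks
    return data, manifest


def write_fixture_dir(config: SyntheticConfig, outdir, id_prefix: str = "syn") -> dict:
    """Write FASTA / .pssm / .ss2 / .rsa / interval files a real run would consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data, manifest, raw_tracks = generate_dataset(config, id_prefix=id_prefix, return_tracks=True)

    intervals = {}
    with open(outdir / "sequences.fasta", "w") as fasta:
        for seq, (pssm, sequence, ss, rsa) in zip(data, raw_tracks):
            pid = seq.observation.sequence_id
            fasta.write(f">{pid}\n{sequence}\n")
            _write_pssm_ascii(outdir / f"{pid}.pssm", sequence, pssm.scores)
            _write_ss2(outdir / f"{pid}.ss2", sequence, ss)
            _write_rsa(outdir / f"{pid}.rsa", sequence, rsa)
            ivs = labels_to_intervals(seq.labels)
            if ivs:
                intervals[pid] = ivs
    write_interval_table(intervals, outdir / "disorder_intervals.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_pssm_ascii(path, sequence: str, scores: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(feat.AA_ORDER_PSIBLAST) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, scores), start=1):
            vals = " ".join(f"{v:7.3f}" for v in row)
            fh.write(f"{i:5d} {aa} {vals}\n")


def _write_ss2(path, sequence: str, track: feat.SecondaryStructureTrack) -> None:
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (synthetic)\n\n")
        for i, (aa, cls) in enumerate(zip(sequence, track.classes), start=1):
            conf = {"C": (1.0, 0.0, 0.0), "H": (0.0, 1.0, 0.0), "E": (0.0, 0.0, 1.0)}[cls]
            fh.write(f"{i:4d} {aa} {cls}  {conf[0]:5.3f} {conf[1]:5.3f} {conf[2]:5.3f}\n")


def _write_rsa(path, sequence: str, track: feat.RSATrack) -> None:
    with open(path, "w") as fh:
        fh.write("# index residue rsa_fraction (synthetic)\n")
        for i, (aa, v) in enumerate(zip(sequence, track.values), start=1):
            fh.write(f"{i}\t{aa}\t{v:.4f}\n")
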