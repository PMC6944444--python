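"""Synthetic NLR repertoire generator with per-record ground truth.

Emulates the statistical structure the downstream analysis assumes:

* multi-family repertoires whose N-terminal domains descend from distinct
  random family ancestors (high within-, low between-family identity);
* one "helper" family whose members carry an intact, highly conserved
  ~21-residue N-terminal motif, optionally preceded by a few jitter
  residues (small N-terminal extensions);
* "sensor" families whose copy of the motif has degenerated by extra
  per-site substitution, a fraction of which additionally carry a long
  (~600 aa) unstructured N-terminal extension domain (NTD) displacing the
  coiled-coil region deep into the protein;
* an alignable NB-ARC-like core containing exactly one Walker-A p-loop
  word, mutated hierarchically (family ancestor, then member) so families
  are monophyletic on the core;
* non-NLR decoys of pure background sequence guaranteed to lack a p-loop.

Every record is paired with a :class:`SyntheticTruth` row so motif
recovery, clustering and classification can be scored exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import AMINO_ACIDS, SequenceRecord

PLOOP_PATTERN = r"G.{4}GK[ST]"

# Fixed NB-ARC-like core used by default: 300 residues, single Walker-A
# word GMGGLGKT at 1-based position 11.
NBARC_TEMPLATE = (
    "LMEWQSDHLSGMGGLGKTSRHDISGMVSCSCFVWMKGQWTMVNSFRWKWVQCLTLAFNCE"
    "YDVMYPILNNSVAQPQIFPASSPMTIPQRCRIPFWLWSPDCTSMQGERETVSKECCWVGV"
    "VNKTFINPRPPILLEDYGTQLGIHMFSWHWLFPKMLFGVFYVMWEWTILYGTANICVQDM"
    "DNVLEMWMGPDDPFFFAFDHKMDQCQIHGDQPNWVSSERCTMCLHTFHPAIGPWHFSCNW"
    "MQHKGKENSPFWMRRMCWNYIPMNMHATNSNCMYMRHWWKLHNYMVPKQSQMLDTSLRTF"
)

#: 0-based offset of the p-loop word within :data:`NBARC_TEMPLATE`; the
#: calibrated ``offset_to_nbarc`` for :func:`madascan.nlrome.annotate_domains`.
PLOOP_OFFSET_IN_TEMPLATE = 10

#: A concrete instantiation of the MADA-like 21-residue consensus used as
#: the default planted motif.
DEFAULT_MOTIF = "MADAEVSFAVGKLTKLLENEL"

TRUTH_COLUMNS = ("record_id", "role", "family_id", "motif_present", "motif_start", "nbarc_start")


@dataclass
class SimConfig:
    """Study conditions for one synthetic repertoire.

    Defaults are the package's reference conditions: 3 families of 40
    members (family 1 = helpers) plus 30 decoys, a 21-residue motif at
    per-column conservation 0.9, 90% of helpers with an intact motif,
    sensor motifs decayed by an extra 0.4 per-site substitution rate, 55%
    of sensors carrying a ~600-residue NTD, and up to 6 jitter residues
    before intact motifs.
    """

    n_families: int = 3
    seqs_per_family: int = 40
    motif_width: int = 21
    motif_consensus: str = DEFAULT_MOTIF
    motif_conservation: float = 0.9
    helper_motif_fraction: float = 0.9
    sensor_decay_rate: float = 0.4
    ntd_fraction: float = 0.55
    ntd_length_mean: int = 600
    extension_jitter: int = 6
    nbarc_template: str = NBARC_TEMPLATE
    decoy_count: int = 30
    seed: int = 0
    # repertoire texture (not part of the core conditions)
    linker_length: int = 90
    family_divergence: float = 0.06
    member_mutation_rate: float = 0.03
    linker_mutation_rate: float = 0.3
    tail_length: int = 150

    def __post_init__(self) -> None:
        for name in (
            "motif_conservation",
            "helper_motif_fraction",
            "sensor_decay_rate",
            "ntd_fraction",
            "family_divergence",
            "member_mutation_rate",
            "linker_mutation_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.motif_width < 4:
            raise ValueError("motif_width must be >= 4")
        if len(self.motif_consensus) != self.motif_width:
            raise ValueError(
                "motif_consensus length must equal motif_width "
                f"({len(self.motif_consensus)} != {self.motif_width})"
            )
        if self.n_families < 1 or self.seqs_per_family < 1:
            raise ValueError("need at least one family with one member")
        matches = re.findall(PLOOP_PATTERN, self.nbarc_template)
        if len(matches) != 1:
            raise ValueError(
                f"nbarc_template must contain exactly one p-loop word, found {len(matches)}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth for one generated record."""

    record_id: str
    role: str  # helper | sensor | decoy
    family_id: int  # 0 for decoys
    motif_present: bool
    motif_start: Optional[int] = None  # 1-based
    nbarc_start: Optional[int] = None  # 1-based

    def __post_init__(self) -> None:
        if self.role not in ("helper", "sensor", "decoy"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.motif_present and (self.motif_start is None or self.motif_start < 1):
            raise ValueError("motif_present requires a positive motif_start")
        if self.role == "decoy" and self.nbarc_start is not None:
            raise ValueError("decoys have no NB-ARC")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    exact_start: int = 0


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: tuple[int, int] | None = None) -> str:
    """Substitute each site to a random *different* residue with prob ``rate``.

    ``protected`` is a half-open 0-based interval left untouched.
    """
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if protected is not None and protected[0] <= i < protected[1]:
            continue
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _sample_motif(rng: np.random.Generator, consensus: str, conservation: float,
                  extra_decay: float = 0.0) -> str:
    """Column-wise motif sample: consensus residue with probability
    ``conservation * (1 - extra_decay)``, else a random other residue."""
    keep = conservation * (1.0 - extra_decay)
    out = []
    for c in consensus:
        if rng.random() < keep:
            out.append(c)
        else:
            choices = AMINO_ACIDS.replace(c, "")
            out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _first_ploop(seq: str) -> Optional[int]:
    m = re.search(PLOOP_PATTERN, seq)
    return m.start() if m else None


def generate_repertoire(config: SimConfig) -> tuple[list[SequenceRecord], list[SyntheticTruth]]:
    """Generate a repertoire and its truth table.

    Deterministic for a fixed ``config.seed``.  Family 1 members are
    helpers, families 2..n are sensors, plus ``decoy_count`` decoys.
    Records are regenerated (bounded retries) if a mutation accidentally
    creates a p-loop word upstream of the planted one, so the first
    Walker-A match always anchors the true NB-ARC start.
    """
    rng = np.random.default_rng(config.seed)
    template = config.nbarc_template
    ploop_off = _first_ploop(template)
    records: list[SequenceRecord] = []
    truths: list[SyntheticTruth] = []

    ancestors = {
        fam: _random_protein(rng, config.linker_length)
        for fam in range(1, config.n_families + 1)
    }
    family_cores = {
        fam: _mutate(rng, template, config.family_divergence,
                     protected=(ploop_off, ploop_off + 8))
        for fam in range(1, config.n_families + 1)
    }

    for fam in range(1, config.n_families + 1):
        role = "helper" if fam == 1 else "sensor"
        for member in range(1, config.seqs_per_family + 1):
            rec_id = f"{role}_f{fam}_{member:03d}"
            for _attempt in range(50):
                linker = _mutate(rng, ancestors[fam], config.linker_mutation_rate)
                core = _mutate(rng, family_cores[fam], config.member_mutation_rate,
                               protected=(ploop_off, ploop_off + 8))
                tail = _random_protein(rng, config.tail_length)

                intact = role == "helper" and rng.random() < config.helper_motif_fraction
                prefix = ""
                if role == "sensor" and rng.random() < config.ntd_fraction:
                    ntd_len = max(450, int(rng.normal(config.ntd_length_mean, 50)))
                    prefix = _random_protein(rng, ntd_len)
                jitter = int(rng.integers(0, config.extension_jitter + 1)) if intact else 0
                jitter_seq = _random_protein(rng, jitter)

                if intact:
                    motif = _sample_motif(rng, config.motif_consensus,
                                          config.motif_conservation)
                else:
                    motif = _sample_motif(rng, config.motif_consensus,
                                          config.motif_conservation,
                                          extra_decay=config.sensor_decay_rate)

                nterm = prefix + jitter_seq + motif + linker
                seq = nterm + core + tail
                nbarc_start = len(nterm) + 1  # 1-based
                if _first_ploop(seq) == len(nterm) + ploop_off:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError(f"could not place a unique p-loop for {rec_id}")

            motif_start = len(prefix) + jitter + 1 if intact else None
            records.append(SequenceRecord(
                id=rec_id, residues=seq, species=f"species{fam}", annotation="NLR"))
            truths.append(SyntheticTruth(
                record_id=rec_id, role=role, family_id=fam,
                motif_present=intact, motif_start=motif_start,
                nbarc_start=nbarc_start))

    for d in range(1, config.decoy_count + 1):
        rec_id = f"decoy_{d:03d}"
        for _attempt in range(200):
            seq = _random_protein(rng, int(rng.integers(250, 600)))
            if _first_ploop(seq) is None:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a p-loop-free decoy")
        records.append(SequenceRecord(
            id=rec_id, residues=seq, species="decoyome", annotation="non-NLR"))
        truths.append(SyntheticTruth(
            record_id=rec_id, role="decoy", family_id=0, motif_present=False))

    return records, truths


def truth_confusion(truth: Sequence[SyntheticTruth], hits, cutoff: float) -> ConfusionCounts:
    """2x2 confusion of motif presence at a bit-score cutoff.

    ``hits`` are :class:`madascan.hmm.HmmHit`-like objects (``record_id``,
    ``score``, ``start``).  A record is predicted positive when its best
    hit scores >= ``cutoff``; truth positive means an intact motif was
    planted.  ``exact_start`` counts true positives whose reported start
    equals the planted start.
    """
    by_id = {t.record_id: t for t in truth}
    best: dict[str, object] = {}
    for hit in hits:
        if hit.record_id not in by_id:
            raise KeyError(f"hit for unknown record id {hit.record_id!r}")
        prev = best.get(hit.record_id)
        if prev is None or hit.score > prev.score:
            best[hit.record_id] = hit
    counts = ConfusionCounts()
    for rec_id, t in by_id.items():
        hit = best.get(rec_id)
        predicted = hit is not None and hit.score >= cutoff
        if t.motif_present and predicted:
            counts.tp += 1
            if hit.start == t.motif_start:
                counts.exact_start += 1
        elif t.motif_present:
            counts.fn += 1
        elif predicted:
            counts.fp += 1
        else:
            counts.tn += 1
    return counts


def write_truth(truths: Sequence[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write("\t".join([
                t.record_id, t.role, str(t.family_id),
                "1" if t.motif_present else "0",
                "" if t.motif_start is None else str(t.motif_start),
                "" if t.nbarc_start is None else str(t.nbarc_start),
            ]) + "\n")


def read_truth(path: str | Path) -> list[SyntheticTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth header {header}")
        for line in fh:
            rec_id, role, fam, present, start, nbarc = line.rstrip("\n").split("\t")
            truths.append(SyntheticTruth(
                record_id=rec_id, role=role, family_id=int(fam),
                motif_present=present == "1",
                motif_start=int(start) if start else None,
                nbarc_start=int(nbarc) if nbarc else None))
    return truths


def write_config(config: SimConfig, path: str | Path) -> None:
    """Flat key-value config file (one ``key = value`` per line)."""
    with open(path, "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)}\n")


def read_config(path: str | Path, **overrides) -> SimConfig:
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(SimConfig)}
    defaults = SimConfig()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    kwargs.update(overrides)
    return SimConfig(**kwargs)
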