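"""The six sequence-scoring modules and their training machinery.

Donor and acceptor modules are splice-site classifiers trained on
annotated junctions versus random in-gene sites; the exon and intron
modules are PSI regressors trained on MPRA-style random-sequence
libraries. Each module's score is the network output *before* the final
sigmoid, so that score differences live on the logit scale.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import nn
from .genome_io import Genome, GenomeAnnotation, one_hot, one_hot_batch, reverse_complement
from .variant_mapping import WindowSpec

MODULE_KINDS = ("donor", "acceptor", "exon5p", "exon3p", "intron5p", "intron3p")

#: kinds whose input length is fixed by the splice-site window
FIXED_LENGTH_KINDS = {"donor": WindowSpec().donor_len, "acceptor": WindowSpec().acceptor_len}

DEFAULT_HYPERPARAMS = {
    "donor": {"hidden": (64, 32), "dropout": 0.2},
    "acceptor": {"filters": 32, "width": 15, "dropout": 0.2},
    "exon": {"filters": 128, "width": 15},
    "intron": {"filters": 256, "width": 15},
}


@dataclass
class LabeledSequenceSet:
    """Sequences with labels in [0, 1] and optional split / task tags.

    Labels are 0/1 for splice-site classification and fractional PSI
    for the exon and intron modules; both are fit with the same
    cross-entropy loss. ``task`` tags ('5p' / '3p') route samples to the
    heads of a two-headed exon or intron network.
    """

    sequences: list[str]
    labels: np.ndarray
    split: np.ndarray | None = None
    task: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if len(self.sequences) != self.labels.size:
            raise ValueError("sequence/label length mismatch")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 1):
            raise ValueError("labels must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequences)

    def to_frame(self):
        import pandas as pd

        data = {"sequence": self.sequences, "label": self.labels}
        if self.split is not None:
            data["split"] = self.split
        if self.task is not None:
            data["task"] = self.task
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df) -> "LabeledSequenceSet":
        return cls(
            sequences=list(df["sequence"]),
            labels=df["label"].to_numpy(),
            split=df["split"].to_numpy() if "split" in df else None,
            task=df["task"].to_numpy() if "task" in df else None,
        )


@dataclass
class ScoringModule:
    """One trained (or initialized) scoring module.

    ``score`` returns the pre-activation value; ``sigmoid(score)`` is
    the module's probability / PSI prediction.
    """

    kind: str
    net: nn.Sequential
    hyperparams: dict

    def __post_init__(self):
        if self.kind not in MODULE_KINDS:
            raise ValueError(f"unknown module kind {self.kind!r}")

    @property
    def input_length(self) -> int | None:
        return FIXED_LENGTH_KINDS.get(self.kind)

    def score(self, sequence: str) -> float:
        if self.input_length is not None and len(sequence) != self.input_length:
            raise ValueError(
                f"{self.kind} module expects length {self.input_length}, "
                f"got {len(sequence)}"
            )
        if len(sequence) == 0:
            return 0.0  # an absent flank contributes no score
        x = one_hot(sequence)[None]
        return float(self.net.forward(x, train=False).reshape(-1)[0])

    def score_batch(self, sequences: Sequence[str]) -> np.ndarray:
        x = one_hot_batch(sequences)
        return self.net.forward(x, train=False).reshape(-1)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.net.params()))


def score_sequence(module: ScoringModule, sequence: str) -> float:
    """Pre-sigmoid score of ``sequence`` under ``module``."""
    return module.score(sequence)


class PairedSequenceNet:
    """Two-headed exon or intron network sharing one convolution trunk.

    The trunk (conv -> ReLU -> global average pooling) is shared between
    a 5' and a 3' head so both MPRA libraries inform the same filters;
    after training, :meth:`split` hands the trunk (by reference, weights
    shared) to two single-head scoring modules.
    """

    def __init__(self, region: str, hyperparams: dict, seed: int):
        if region not in ("exon", "intron"):
            raise ValueError(f"paired nets are built for exon/intron, not {region!r}")
        hp = {**DEFAULT_HYPERPARAMS[region], **(hyperparams or {})}
        rng = np.random.default_rng(seed)
        self.region = region
        self.hyperparams = hp
        self.trunk = nn.Sequential([
            nn.Conv1D(4, hp["filters"], hp["width"], "same", rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
        ])
        self.heads = {
            "5p": nn.Sequential([nn.Dense(hp["filters"], 1, rng)]),
            "3p": nn.Sequential([nn.Dense(hp["filters"], 1, rng)]),
        }

    def params(self):
        return self.trunk.params() + self.heads["5p"].params() + self.heads["3p"].params()

    def grads(self):
        return self.trunk.grads() + self.heads["5p"].grads() + self.heads["3p"].grads()

    def state(self):
        return self.trunk.state()

    def forward_task(self, x, task: str, train=False, rng=None):
        h = self.trunk.forward(x, train=train, rng=rng)
        return self.heads[task].forward(h, train=train, rng=rng)

    def backward_task(self, g, task: str):
        # stale gradients of the idle head must not leak into the update
        other = "3p" if task == "5p" else "5p"
        for garr in self.heads[other].grads():
            garr[...] = 0.0
        gh = self.heads[task].backward(g)
        return self.trunk.backward(gh)

    def split(self) -> tuple[ScoringModule, ScoringModule]:
        prefix = self.region
        mods = []
        for task in ("5p", "3p"):
            net = nn.Sequential(self.trunk.layers + self.heads[task].layers)
            mods.append(ScoringModule(kind=f"{prefix}{task}", net=net, hyperparams=self.hyperparams))
        return tuple(mods)


def _build_single(kind: str, hyperparams: dict | None, seed: int) -> ScoringModule:
    rng = np.random.default_rng(seed)
    ws = WindowSpec()
    if kind == "donor":
        hp = {**DEFAULT_HYPERPARAMS["donor"], **(hyperparams or {})}
        h1, h2 = hp["hidden"]
        layers = [
            nn.Flatten(),
            nn.Dense(4 * ws.donor_len, h1, rng),
            nn.ReLU(),
            nn.BatchNorm(h1),
            nn.Dropout(hp["dropout"]),
            nn.Dense(h1, h2, rng),
            nn.ReLU(),
            nn.BatchNorm(h2),
            nn.Dropout(hp["dropout"]),
            nn.Dense(h2, 1, rng),
        ]
    elif kind == "acceptor":
        hp = {**DEFAULT_HYPERPARAMS["acceptor"], **(hyperparams or {})}
        f, w = hp["filters"], hp["width"]
        conv_out = ws.acceptor_len - w + 1
        layers = [
            nn.Conv1D(4, f, w, "valid", rng),
            nn.ReLU(),
            nn.Conv1D(f, f, 1, "valid", rng),
            nn.ReLU(),
            nn.BatchNorm(f),
            nn.Dropout(hp["dropout"]),
            nn.Flatten(),
            nn.Dense(conv_out * f, 1, rng),
        ]
    elif kind in ("exon5p", "exon3p", "intron5p", "intron3p"):
        region = "exon" if kind.startswith("exon") else "intron"
        hp = {**DEFAULT_HYPERPARAMS[region], **(hyperparams or {})}
        layers = [
            nn.Conv1D(4, hp["filters"], hp["width"], "same", rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Dense(hp["filters"], 1, rng),
        ]
    else:
        raise ValueError(f"unknown module kind {kind!r}")
    return ScoringModule(kind=kind, net=nn.Sequential(layers), hyperparams=hp)


def build_module(kind: str, hyperparams: dict | None = None, seed: int = 0) -> ScoringModule:
    """Build an untrained scoring module of the given kind."""
    return _build_single(kind, hyperparams, seed)


def build_paired_module(region: str, hyperparams: dict | None = None, seed: int = 0) -> PairedSequenceNet:
    """Build the two-headed exon or intron network for joint training."""
    return PairedSequenceNet(region, hyperparams, seed)


def build_module_set(seed: int = 0, hyperparams: Mapping[str, dict] | None = None) -> dict[str, ScoringModule]:
    """One (untrained) module of each of the six kinds, seeded.

    Exon and intron pairs come from split two-headed networks, so the
    shared-trunk weight identity holds from the start.
    """
    hyperparams = hyperparams or {}
    modules: dict[str, ScoringModule] = {
        "donor": build_module("donor", hyperparams.get("donor"), seed),
        "acceptor": build_module("acceptor", hyperparams.get("acceptor"), seed + 1),
    }
    exon5p, exon3p = build_paired_module("exon", hyperparams.get("exon"), seed + 2).split()
    intron5p, intron3p = build_paired_module("intron", hyperparams.get("intron"), seed + 3).split()
    modules.update({"exon5p": exon5p, "exon3p": exon3p, "intron5p": intron5p, "intron3p": intron3p})
    return modules


# ---------------------------------------------------------------------------
# splice-site training data


def _site_window(genome: Genome, contig: str, strand: str, boundary: int,
                 kind: str, ws: WindowSpec) -> str | None:
    """Splice-site window around a junction, transcript-oriented.

    ``boundary`` is the genomic coordinate of the junction: the first
    intronic base for a plus-strand donor, the first exonic base for a
    plus-strand acceptor (mirrored on minus). Returns None when the
    window leaves the contig.
    """
    if kind == "donor":
        span = (boundary - ws.donor_exonic, boundary + ws.donor_intronic) if strand == "+" \
            else (boundary - ws.donor_intronic, boundary + ws.donor_exonic)
    else:
        span = (boundary - ws.acceptor_intronic, boundary + ws.acceptor_exonic) if strand == "+" \
            else (boundary - ws.acceptor_exonic, boundary + ws.acceptor_intronic)
    if span[0] < 0 or span[1] > genome.contig_length(contig):
        return None
    seq = genome.fetch(contig, *span)
    return reverse_complement(seq) if strand == "-" else seq


def _is_canonical(genome: Genome, contig: str, strand: str, boundary: int, kind: str) -> bool:
    if kind == "donor":
        dinuc = genome.fetch(contig, boundary, boundary + 2) if strand == "+" \
            else reverse_complement(genome.fetch(contig, boundary - 2, boundary))
        return dinuc == "GT"
    dinuc = genome.fetch(contig, boundary - 2, boundary) if strand == "+" \
        else reverse_complement(genome.fetch(contig, boundary, boundary + 2))
    return dinuc == "AG"


def make_splice_site_training_set(
    annotation: GenomeAnnotation,
    genome: Genome,
    kind: str,
    neg_ratio: float = 1.5,
    canonical_frac: float = 0.5,
    seed: int = 0,
    windows: WindowSpec = WindowSpec(),
) -> LabeledSequenceSet:
    """Positive (annotated) and negative (random in-gene) splice sites.

    Positives are the unique annotated boundaries, canonical or not.
    Negatives are drawn within the genes that contributed positives,
    away from any positive site, with approximately ``canonical_frac``
    of them carrying the canonical GT (donor) or AG (acceptor)
    dinucleotide at the would-be junction.
    """
    if kind not in ("donor", "acceptor"):
        raise ValueError("kind must be 'donor' or 'acceptor'")
    if not 0.0 <= canonical_frac <= 1.0:
        raise ValueError("canonical_frac must be in [0, 1]")
    if not annotation.exons:
        raise ValueError("annotation has no exons")
    rng = np.random.default_rng(seed)
    span = windows.donor_len if kind == "donor" else windows.acceptor_len

    # positives are splice junctions: boundaries between consecutive exons
    # of a gene (terminal exon ends are transcript ends, not splice sites)
    by_gene: dict[str, list] = {}
    for exon in annotation.exons:
        by_gene.setdefault(exon.gene_id, []).append(exon)
    pos_boundaries: dict[tuple[str, str], set[int]] = {}
    sequences, labels = [], []
    for exons in by_gene.values():
        exons = sorted(exons, key=lambda e: e.start)
        for left, right in zip(exons, exons[1:]):
            strand = left.strand
            if kind == "donor":
                boundary = left.end if strand == "+" else right.start
            else:
                boundary = right.start if strand == "+" else left.end
            key = (left.contig, strand)
            if boundary in pos_boundaries.setdefault(key, set()):
                continue
            seq = _site_window(genome, left.contig, strand, boundary, kind, windows)
            if seq is None:
                continue
            pos_boundaries[key].add(boundary)
            sequences.append(seq)
            labels.append(1.0)
    if not sequences:
        raise ValueError("no splice junctions found (single-exon genes only?)")

    n_pos = len(sequences)
    n_neg = int(round(neg_ratio * n_pos))
    n_canonical = int(round(canonical_frac * n_neg))
    genes = [g for g in annotation.genes if (g.contig, g.strand) in pos_boundaries]
    if not genes:
        raise ValueError("no genes contribute positive sites")

    margin = span + 2
    for i in range(n_neg):
        want_canonical = i < n_canonical
        for _ in range(20000):
            gene = genes[rng.integers(len(genes))]
            lo, hi = gene.start + margin, gene.end - margin
            if hi <= lo:
                continue
            b = int(rng.integers(lo, hi))
            taken = pos_boundaries[(gene.contig, gene.strand)]
            if any(abs(b - p) < span for p in taken):
                continue
            if _is_canonical(genome, gene.contig, gene.strand, b, kind) != want_canonical:
                continue
            seq = _site_window(genome, gene.contig, gene.strand, b, kind, windows)
            if seq is None:
                continue
            sequences.append(seq)
            labels.append(0.0)
            break
        else:
            raise ValueError(
                "could not place a negative site; genes too short for the "
                "requested number of negatives"
            )

    split = np.where(rng.random(len(sequences)) < 0.8, "train", "val")
    return LabeledSequenceSet(sequences=sequences, labels=np.array(labels), split=split)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


def _encode(dataset: LabeledSequenceSet) -> np.ndarray:
    return one_hot_batch(dataset.sequences)


def train_module(
    module: ScoringModule | PairedSequenceNet,
    dataset: LabeledSequenceSet,
    lr: float = 1e-3,
    batch_size: int = 64,
    epochs: int = 100,
    patience: int = 5,
    seed: int = 0,
) -> tuple[ScoringModule | PairedSequenceNet, TrainingLog]:
    """Fit a module with Adam on cross-entropy loss.

    Data are split 80/20 into train/validation (or per the dataset's
    own split tags); the weights of the epoch with the smallest
    validation loss are restored before returning. Training stops early
    after ``patience`` epochs without validation improvement.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    paired = isinstance(module, PairedSequenceNet)
    if paired and dataset.task is None:
        raise ValueError("two-headed module requires task tags ('5p'/'3p')")

    rng = np.random.default_rng(seed)
    X = _encode(dataset)
    y = dataset.labels
    if dataset.split is not None:
        train_idx = np.flatnonzero(dataset.split == "train")
        val_idx = np.flatnonzero(dataset.split == "val")
    else:
        perm = rng.permutation(len(dataset))
        cut = int(round(0.8 * len(dataset)))
        train_idx, val_idx = perm[:cut], perm[cut:]
    if len(train_idx) == 0 or len(val_idx) == 0:
        # tiny datasets: validate on the training data itself
        train_idx = np.arange(len(dataset))
        val_idx = train_idx

    tasks = dataset.task if paired else None
    if paired:
        params, grads, state = module.params(), module.grads(), module.state()
    else:
        params, grads, state = module.net.params(), module.net.grads(), module.net.state()
    opt = nn.Adam(lr=lr)
    log = TrainingLog()
    best = None
    stale = 0

    def val_loss() -> float:
        total, n = 0.0, 0
        if paired:
            for task in ("5p", "3p"):
                idx = val_idx[tasks[val_idx] == task]
                if idx.size == 0:
                    continue
                z = module.forward_task(X[idx], task, train=False)
                loss, _ = nn.bce_with_logits(z, y[idx])
                total += loss * idx.size
                n += idx.size
        else:
            z = module.net.forward(X[val_idx], train=False)
            loss, _ = nn.bce_with_logits(z, y[val_idx])
            total, n = loss * val_idx.size, val_idx.size
        return total / max(n, 1)

    for epoch in range(epochs):
        # task-homogeneous mini-batches, interleaved in shuffled order
        batches: list[tuple[np.ndarray, str | None]] = []
        if paired:
            for task in ("5p", "3p"):
                idx = train_idx[tasks[train_idx] == task]
                idx = idx[rng.permutation(idx.size)]
                batches += [(idx[i:i + batch_size], task) for i in range(0, idx.size, batch_size)]
            rng.shuffle(batches)
        else:
            idx = train_idx[rng.permutation(train_idx.size)]
            batches = [(idx[i:i + batch_size], None) for i in range(0, idx.size, batch_size)]

        tr_total, tr_n = 0.0, 0
        for bidx, task in batches:
            xb, yb = X[bidx], y[bidx]
            if paired:
                z = module.forward_task(xb, task, train=True, rng=rng)
                loss, dz = nn.bce_with_logits(z, yb)
                module.backward_task(dz.reshape(z.shape), task)
            else:
                z = module.net.forward(xb, train=True, rng=rng)
                loss, dz = nn.bce_with_logits(z, yb)
                module.net.backward(dz.reshape(z.shape))
            opt.step(params, grads)
            tr_total += loss * bidx.size
            tr_n += bidx.size

        vl = val_loss()
        log.epochs.append({"epoch": epoch, "train_loss": tr_total / max(tr_n, 1), "val_loss": vl})
        if vl < log.best_val_loss:
            log.best_val_loss = vl
            log.best_epoch = epoch
            best = nn.snapshot(params) + nn.snapshot(state)
            stale = 0
        else:
            stale += 1
            if stale > patience:
                break

    if best is not None:
        nn.restore(params, best[:len(params)])
        nn.restore(state, best[len(params):])
    return module, log


def random_search(
    space: Mapping[str, Sequence],
    trials: int,
    seed: int,
    evaluate: Callable[[dict], float],
) -> tuple[dict, list[tuple[dict, float]]]:
    """Seeded random hyperparameter search minimizing validation loss.

    Each trial samples one combination from ``space`` and scores it with
    ``evaluate`` (which should return the validation loss); the best
    combination and the full trial history are returned.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    history = []
    best, best_loss = None, np.inf
    for _ in range(trials):
        config = {k: v[rng.integers(len(v))] for k, v in space.items()}
        loss = evaluate(config)
        history.append((config, loss))
        if loss < best_loss:
            best, best_loss = config, loss
    return best, history


# ---------------------------------------------------------------------------
# serialization


def save_module(module: ScoringModule, path: str | Path) -> None:
    """Write a module (architecture spec + weights) to one .npz file."""
    hp = dict(module.hyperparams)
    if "hidden" in hp:
        hp["hidden"] = list(hp["hidden"])
    spec = json.dumps({"kind": module.kind, "hyperparams": hp})
    arrays = {f"p{i}": a for i, a in enumerate(module.net.params())}
    arrays.update({f"s{i}": a for i, a in enumerate(module.net.state())})
    np.savez(path, spec=np.array(spec), **arrays)


def load_module(path: str | Path) -> ScoringModule:
    with np.load(path) as npz:
        meta = json.loads(str(npz["spec"]))
        hp = meta["hyperparams"]
        if "hidden" in hp:
            hp["hidden"] = tuple(hp["hidden"])
        module = _build_single(meta["kind"], hp, seed=0)
        params = module.net.params()
        state = module.net.state()
        for i, a in enumerate(params):
            a[...] = npz[f"p{i}"]
        for i, a in enumerate(state):
            a[...] = npz[f"s{i}"]
    return module


def save_module_set(modules: Mapping[str, ScoringModule], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, module in modules.items():
        save_module(module, directory / f"{kind}.npz")


def load_module_set(directory: str | Path) -> dict[str, ScoringModule]:
    directory = Path(directory)
    modules = {}
    for kind in MODULE_KINDS:
        path = directory / f"{kind}.npz"
        if not path.exists():
            raise FileNotFoundError(f"missing module weights: {path}")
        modules[kind] = load_module(path)
    return modules
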