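"""Self-organizing-map clustering of fixed-length amplicon reads.

Reads of a fixed nominal length (200 nt by default) are one-hot encoded over
the alphabet A/C/G/T/N and clustered on a two-dimensional SOM grid (20 x 20
by default, 10,000 rounds of training). Node profiles are position-weight
matrices; the distance between a read and a node is the "soft Hamming"
distance

    d(read, node) = sum_pos (1 - w[pos, base(read, pos)])

which reduces to the ordinary integer Hamming distance whenever the node
profile is itself one-hot. After mapping every read to its best-matching
unit, each cluster's cohesion is measured as the mean pairwise Pearson
correlation of the members' one-hot vectors; loose clusters (R < 0.95) are
re-clustered once on a smaller grid (10 x 10), and a representative read
(the member most correlated with the cluster's mean profile) is selected
per final cluster.

The trainer presents one uniformly sampled read per round ("rounds" counts
single-read presentations); learning rate decays linearly 0.5 -> 0.01 and
the Gaussian neighborhood radius decays linearly max(grid)/2 -> 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .records import ALPHABET, ReadSet

_CODE = {c: i for i, c in enumerate(ALPHABET)}
_N_CODE = _CODE["N"]
_A = len(ALPHABET)


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable reads."""


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class EncodedReads:
    """Integer-coded reads plus on-demand one-hot views.

    codes: (n_reads, length) uint8 array over ALPHABET indices.
    ids: read identifiers, parallel to rows of `codes`.
    n_discarded: reads dropped for being shorter than the target length.
    """

    codes: np.ndarray
    ids: list[str]
    length: int
    n_discarded: int = 0

    def __len__(self) -> int:
        return self.codes.shape[0]

    @property
    def flat_indices(self) -> np.ndarray:
        """Per-read flat indices into an (length*|alphabet|) one-hot vector."""
        return (np.arange(self.length, dtype=np.int64) * _A)[None, :] + self.codes

    def onehot(self) -> np.ndarray:
        """(n, length*5) binary indicator matrix (full A/C/G/T/N alphabet)."""
        out = np.zeros((len(self), self.length * _A), dtype=np.float32)
        rows = np.repeat(np.arange(len(self)), self.length)
        out[rows, self.flat_indices.ravel()] = 1.0
        return out

    def acgt_onehot(self, rows: np.ndarray | None = None) -> np.ndarray:
        """(m, length*4) indicators over A/C/G/T only; 'N' gives a zero block.

        This is the encoding used for Pearson-correlation cohesion: on the
        4-letter alphabet two fully divergent ACGT reads correlate at -1/3.
        """
        codes = self.codes if rows is None else self.codes[rows]
        m = codes.shape[0]
        out = np.zeros((m, self.length * 4), dtype=np.float32)
        pos = np.tile(np.arange(self.length, dtype=np.int64) * 4, (m, 1))
        keep = codes != _N_CODE
        r = np.repeat(np.arange(m), self.length)[keep.ravel()]
        c = (pos + codes)[keep]
        out[r, c] = 1.0
        return out

    def subset(self, rows: np.ndarray) -> "EncodedReads":
        return EncodedReads(
            codes=self.codes[rows],
            ids=[self.ids[i] for i in rows],
            length=self.length,
            n_discarded=0,
        )


def encode_reads(reads, length: int = 200) -> EncodedReads:
    """One-hot encode reads at a fixed length.

    Accepts a ReadSet, an iterable of sequences, or of (id, sequence) pairs.
    Reads shorter than `length` are discarded (counted in `n_discarded`);
    longer reads are truncated. Non-ACGT symbols map to the 'N' indicator.
    """
    if isinstance(reads, ReadSet):
        items = list(zip(reads.ids, reads.sequences))
    else:
        items = []
        for i, r in enumerate(reads):
            if isinstance(r, str):
                items.append((f"read_{i:06d}", r))
            else:
                items.append((r[0], r[1]))
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_discarded = 0
    for rid, seq in items:
        if len(seq) < length:
            n_discarded += 1
            continue
        codes = np.fromiter(
            (_CODE.get(c, _N_CODE) for c in seq[:length].upper()),
            dtype=np.uint8,
            count=length,
        )
        rows.append(codes)
        kept_ids.append(rid)
    if not rows:
        raise EmptyInputError("no reads of sufficient length to encode")
    return EncodedReads(
        codes=np.vstack(rows), ids=kept_ids, length=length, n_discarded=n_discarded
    )


@dataclass
class SOMCodebook:
    """Trained SOM node profiles.

    weights: (grid_rows*grid_cols, length*5) position-weight matrices;
    after training each node's per-position weights sum to 1.
    """

    grid: tuple[int, int]
    length: int
    weights: np.ndarray
    rounds: int
    seed: int | None

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    def node_coords(self, node: int) -> tuple[int, int]:
        return divmod(node, self.grid[1])

    def consensus(self, node: int) -> str:
        """Majority base per position of a node profile (ties: ACGTN order)."""
        prof = self.weights[node].reshape(self.length, _A)
        return "".join(ALPHABET[i] for i in prof.argmax(axis=1))

    def distances(self, encoded: EncodedReads) -> np.ndarray:
        """Soft-Hamming distances, shape (n_reads, n_nodes)."""
        if encoded.length * _A != self.weights.shape[1]:
            raise ValueError("encoding width does not match codebook")
        # d = L - sum_pos w[pos, base]; gather node weights at read positions,
        # chunked over reads to bound memory
        flat = encoded.flat_indices
        n = len(encoded)
        out = np.empty((n, self.n_nodes), dtype=np.float64)
        step = max(1, 4_000_000 // (self.n_nodes * encoded.length))
        for start in range(0, n, step):
            block = flat[start : start + step]
            sims = self.weights[:, block.ravel()]
            sims = sims.reshape(self.n_nodes, block.shape[0], encoded.length).sum(
                axis=2
            )
            out[start : start + step] = encoded.length - sims.T
        return out


def _grid_sq_distances(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    return (rr[:, None] - rr[None, :]) ** 2 + (cc[:, None] - cc[None, :]) ** 2


def train_som(
    encoded: EncodedReads,
    grid: tuple[int, int] = (20, 20),
    rounds: int = 10_000,
    seed: int | None = None,
    alpha: tuple[float, float] = (0.5, 0.01),
    sigma_end: float = 0.5,
) -> SOMCodebook:
    """Train a SOM codebook on encoded reads.

    Nodes are initialized from reads sampled with replacement. Each round
    presents one uniformly sampled read, finds the best-matching unit by
    minimal soft-Hamming distance (ties: smallest node index in row-major
    order) and pulls all nodes toward the read's one-hot vector with a
    Gaussian neighborhood kernel.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if len(encoded) < 1:
        raise EmptyInputError("cannot train a SOM on zero reads")
    g_rows, g_cols = grid
    n_nodes = g_rows * g_cols
    rng = np.random.default_rng(seed)
    flat = encoded.flat_indices
    L = encoded.length

    W = np.zeros((n_nodes, L * _A), dtype=np.float32)
    init_rows = rng.integers(0, len(encoded), n_nodes)
    W[np.repeat(np.arange(n_nodes), L), flat[init_rows].ravel()] = 1.0

    D2 = _grid_sq_distances(g_rows, g_cols)
    alphas = np.linspace(alpha[0], alpha[1], rounds)
    sigmas = np.linspace(max(g_rows, g_cols) / 2.0, sigma_end, rounds)
    picks = rng.integers(0, len(encoded), rounds)

    for t in range(rounds):
        idx = flat[picks[t]]
        sims = W[:, idx].sum(axis=1)
        bmu = int(np.argmax(sims))  # max similarity == min distance; row-major ties
        h = np.exp(-D2[bmu] / (2.0 * sigmas[t] ** 2))
        sel = np.flatnonzero(h > 1e-6)
        ah = (alphas[t] * h[sel]).astype(np.float32)
        # profile <- profile + a*h*(onehot - profile), exploiting onehot sparsity
        Wsel = W[sel]
        Wsel *= (1.0 - ah)[:, None]
        Wsel[:, idx] += ah[:, None]
        W[sel] = Wsel

    return SOMCodebook(grid=grid, length=L, weights=W, rounds=rounds, seed=seed)


@dataclass
class ReadCluster:
    """One final read cluster of a sample."""

    cluster_id: str
    members: np.ndarray  # row indices into the sample's EncodedReads
    node: tuple[int, int]
    cohesion: float | None = None
    representative: int | None = None  # row index into EncodedReads
    is_subcluster: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ReadClusterSet:
    """Partition of a sample's encoded reads into clusters."""

    clusters: list[ReadCluster]
    n_reads: int

    def __post_init__(self) -> None:
        total = sum(c.size for c in self.clusters)
        if total != self.n_reads:
            raise ValueError(
                f"clusters cover {total} reads, expected {self.n_reads}"
            )

    def labels(self) -> np.ndarray:
        out = np.full(self.n_reads, -1, dtype=np.int64)
        for i, c in enumerate(self.clusters):
            out[c.members] = i
        return out


def assign_to_nodes(encoded: EncodedReads, codebook: SOMCodebook) -> ReadClusterSet:
    """Map every read to its best-matching node (ties: smallest node index)."""
    d = codebook.distances(encoded)
    bmus = d.argmin(axis=1)
    clusters = []
    for node in np.unique(bmus):
        members = np.flatnonzero(bmus == node)
        r, c = codebook.node_coords(int(node))
        clusters.append(
            ReadCluster(cluster_id=f"n{r:02d}_{c:02d}", members=members, node=(r, c))
        )
    return ReadClusterSet(clusters=clusters, n_reads=len(encoded))


def cluster_cohesion(
    members: np.ndarray,
    encoded: EncodedReads,
    max_pairs: int = 10_000,
    seed: int | None = None,
) -> float:
    """Mean pairwise Pearson correlation of member one-hot vectors.

    Singletons score 1 by convention. Above `max_pairs` member pairs, a
    seeded uniform sample of `max_pairs` distinct pairs is used. A read
    whose indicator vector has zero variance (all-N) contributes r = 0.
    """
    m = len(members)
    if m < 1:
        raise EmptyInputError("cohesion of an empty cluster is undefined")
    if m == 1:
        return 1.0
    X = encoded.acgt_onehot(rows=np.asarray(members))
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = np.inf  # all-N reads: define r = 0 against anything
    Xn = X / norms[:, None]
    n_pairs = m * (m - 1) // 2
    if n_pairs <= max_pairs:
        R = Xn @ Xn.T
        iu = np.triu_indices(m, k=1)
        return float(np.clip(R[iu].mean(), -1.0, 1.0))
    rng = np.random.default_rng(seed)
    lin = rng.choice(n_pairs, size=max_pairs, replace=False)
    # decode linear index of upper triangle (i < j)
    i = (m - 2 - np.floor(
        np.sqrt(-8.0 * lin + 4.0 * m * (m - 1) - 7.0) / 2.0 - 0.5
    )).astype(np.int64)
    j = (lin + i + 1 - (m * (m - 1) // 2) + ((m - i) * (m - i - 1)) // 2).astype(
        np.int64
    )
    return float(np.clip((Xn[i] * Xn[j]).sum(axis=1).mean(), -1.0, 1.0))


def select_representative(cluster: ReadCluster, encoded: EncodedReads) -> int:
    """Member most correlated with the cluster's mean one-hot profile.

    Ties are broken toward the smallest read index (input order).
    Returns a row index into `encoded`.
    """
    members = np.asarray(cluster.members)
    if len(members) == 0:
        raise EmptyInputError("cannot pick a representative of an empty cluster")
    if len(members) == 1:
        return int(members[0])
    X = encoded.acgt_onehot(rows=members)
    profile = X.mean(axis=0)
    Xc = X - X.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    norms = np.linalg.norm(Xc, axis=1) * np.linalg.norm(pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(norms > 0, (Xc @ pc) / norms, 0.0)
    best = corr.max()
    candidates = members[corr >= best - 1e-12]
    return int(candidates.min())


def subcluster_loose(
    clusterset: ReadClusterSet,
    encoded: EncodedReads,
    threshold: float = 0.95,
    subgrid: tuple[int, int] = (10, 10),
    rounds: int = 10_000,
    seed: int | None = None,
    max_pairs: int = 10_000,
) -> ReadClusterSet:
    """Re-cluster loose clusters (cohesion < threshold) once on a small grid.

    Cohesion must already be set on the input clusters; subclusters replace
    their parent, inherit a derived cluster_id and get fresh cohesion values.
    Subclustering is applied exactly once (no recursion).
    """
    children = np.random.SeedSequence(seed).spawn(len(clusterset.clusters))
    out: list[ReadCluster] = []
    for k, cl in enumerate(clusterset.clusters):
        if cl.cohesion is None:
            raise ValueError("cohesion must be computed before subclustering")
        if cl.cohesion >= threshold or cl.size < 2:
            out.append(cl)
            continue
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        sub_encoded = encoded.subset(np.asarray(cl.members))
        codebook = train_som(sub_encoded, grid=subgrid, rounds=rounds, seed=child_seed)
        sub = assign_to_nodes(sub_encoded, codebook)
        for s in sub.clusters:
            members = np.asarray(cl.members)[s.members]
            coh = cluster_cohesion(
                members, encoded, max_pairs=max_pairs, seed=child_seed
            )
            out.append(
                ReadCluster(
                    cluster_id=f"{cl.cluster_id}.s{s.cluster_id}",
                    members=members,
                    node=s.node,
                    cohesion=coh,
                    is_subcluster=True,
                )
            )
    return ReadClusterSet(clusters=out, n_reads=clusterset.n_reads)


def cluster_sample(
    encoded: EncodedReads,
    grid: tuple[int, int] = (20, 20),
    rounds: int = 10_000,
    cohesion_threshold: float = 0.95,
    subgrid: tuple[int, int] = (10, 10),
    subrounds: int = 10_000,
    max_pairs: int = 10_000,
    seed: int | None = None,
) -> ReadClusterSet:
    """Full per-sample clustering: SOM, cohesion check, one round of
    subclustering, representative selection."""
    ss = np.random.SeedSequence(seed)
    s_train, s_coh, s_sub = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    codebook = train_som(encoded, grid=grid, rounds=rounds, seed=s_train)
    clusterset = assign_to_nodes(encoded, codebook)
    for cl in clusterset.clusters:
        cl.cohesion = cluster_cohesion(
            cl.members, encoded, max_pairs=max_pairs, seed=s_coh
        )
    clusterset = subcluster_loose(
        clusterset,
        encoded,
        threshold=cohesion_threshold,
        subgrid=subgrid,
        rounds=subrounds,
        seed=s_sub,
        max_pairs=max_pairs,
    )
    for cl in clusterset.clusters:
        cl.representative = select_representative(cl, encoded)
    return clusterset


class SequenceSOM(ClusterMixin, BaseEstimator):
    """scikit-learn style SOM clusterer over fixed-length sequences.

    fit(X) accepts a ReadSet, a list of sequences, or an EncodedReads;
    after fitting, `codebook_` holds the trained node profiles and
    `labels_` the per-read best-matching node index.
    """

    def __init__(
        self,
        grid: tuple[int, int] = (20, 20),
        rounds: int = 10_000,
        length: int = 200,
        random_state: int | None = None,
    ):
        self.grid = grid
        self.rounds = rounds
        self.length = length
        self.random_state = random_state

    def _encode(self, X) -> EncodedReads:
        return X if isinstance(X, EncodedReads) else encode_reads(X, self.length)

    def fit(self, X, y=None):
        encoded = self._encode(X)
        self.codebook_ = train_som(
            encoded, grid=self.grid, rounds=self.rounds, seed=self.random_state
        )
        self.encoded_ = encoded
        self.labels_ = self.codebook_.distances(encoded).argmin(axis=1)
        return self

    def predict(self, X) -> np.ndarray:
        encoded = self._encode(X)
        return self.codebook_.distances(encoded).argmin(axis=1)


class AmpliconClusterer(ClusterMixin, BaseEstimator):
    """Full per-sample read clustering pipeline as an estimator.

    fit(X) runs SOM training, cohesion checking, subclustering of loose
    clusters and representative selection; afterwards `clusters_` holds the
    final ReadClusterSet, `labels_` the per-read final-cluster index and
    `representatives_` the (read_id, sequence-row) of each cluster.
    """

    def __init__(
        self,
        grid: tuple[int, int] = (20, 20),
        rounds: int = 10_000,
        cohesion_threshold: float = 0.95,
        subgrid: tuple[int, int] = (10, 10),
        subrounds: int = 10_000,
        max_pairs: int = 10_000,
        length: int = 200,
        random_state: int | None = None,
    ):
        self.grid = grid
        self.rounds = rounds
        self.cohesion_threshold = cohesion_threshold
        self.subgrid = subgrid
        self.subrounds = subrounds
        self.max_pairs = max_pairs
        self.length = length
        self.random_state = random_state

    def fit(self, X, y=None):
        encoded = X if isinstance(X, EncodedReads) else encode_reads(X, self.length)
        self.encoded_ = encoded
        self.n_discarded_ = encoded.n_discarded
        self.clusters_ = cluster_sample(
            encoded,
            grid=self.grid,
            rounds=self.rounds,
            cohesion_threshold=self.cohesion_threshold,
            subgrid=self.subgrid,
            subrounds=self.subrounds,
            max_pairs=self.max_pairs,
            seed=self.random_state,
        )
        self.labels_ = self.clusters_.labels()
        return self
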