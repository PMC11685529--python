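"""The recurrent learning agent: coupled generative and contrastive parts.

The agent mirrors how a human participant is trained in an
artificial-language experiment.  A feedforward ENCODER maps the
6-dimensional scene vector to a latent state ``h``.  The generative
component (WRITER) is an LSTM that, seeded with ``h`` as its initial
hidden state, emits a label character by character; its training signal
is token-wise cross-entropy against the language's ground-truth label.
The contrastive component (READER) is a second LSTM that consumes a
label and maps its final state through a fully-connected head to a
latent ``z``; the NT-Xent objective pulls ``z`` toward the encoding of
the matching scene against in-batch distractors, which is what lets the
agent *guess* the right scene for a label.

The two components are deliberately coupled: a single symbol-embedding
table serves as the input layer of both READER and WRITER and (tied by
transpose) as WRITER's output projection, and the same ENCODER instance
feeds both objectives.  A contrastive update therefore reshapes the
space the writer generates from, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, parameter
from .corpus import (
    DEFAULT_ALPHABET,
    EOS_ID,
    MAX_LABEL_LENGTH,
    PAD_ID,
    Scene,
    Vocabulary,
    encode_scene,
    encode_scenes,
)

SCENE_DIM = 6


@dataclass
class AgentConfig:
    """Hyperparameters of the recurrent agent.

    Defaults follow the reference setting: all hidden sizes 50, loss mix
    L_gen + alpha_con * L_con with alpha_con = 0.1, Adam at learning
    rate 1e-3.
    """

    latent_dim: int = 50
    hidden_dim: int = 50
    embedding_dim: int = 50
    alpha_con: float = 0.1
    contrastive_temperature: float = 0.5
    learning_rate: float = 1e-3
    max_label_length: int = MAX_LABEL_LENGTH
    alphabet: str = DEFAULT_ALPHABET
    seed: int = 0
    fallback_char: str = "a"

    def __post_init__(self):
        if min(self.latent_dim, self.hidden_dim, self.embedding_dim) <= 0:
            raise ValueError("dimensions must be positive")
        if self.alpha_con < 0:
            raise ValueError("alpha_con must be nonnegative")
        if self.contrastive_temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class LossBreakdown:
    """Generative and contrastive loss terms plus their weighted total."""

    generative: float
    contrastive: float
    alpha_con: float

    @property
    def total(self) -> float:
        return self.generative + self.alpha_con * self.contrastive

    def __add__(self, other: "LossBreakdown") -> "LossBreakdown":
        return LossBreakdown(
            self.generative + other.generative,
            self.contrastive + other.contrastive,
            self.alpha_con,
        )


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Agent:
    """One learner with its parameters and optimizer state."""

    def __init__(self, config: AgentConfig):
        self.config = config
        self.vocab = Vocabulary(config.alphabet)
        V = len(self.vocab)
        H, E, L = config.hidden_dim, config.embedding_dim, config.latent_dim
        rng = np.random.default_rng(config.seed)

        # single shared symbol-embedding table; also WRITER's output
        # projection via transpose tying
        self.embedding = parameter(_he(rng, E, (V, E)))
        # ENCODER: one-hidden-layer MLP, scene (6) -> latent/hidden (H)
        self.enc_W1 = parameter(_he(rng, SCENE_DIM, (SCENE_DIM, H)))
        self.enc_b1 = parameter(np.zeros(H))
        self.enc_W2 = parameter(_he(rng, H, (H, H)))
        self.enc_b2 = parameter(np.zeros(H))
        # WRITER LSTM (gates ordered i, f, g, o) + output bias
        self.wr_Wx = parameter(_he(rng, E, (E, 4 * H)))
        self.wr_Wh = parameter(_he(rng, H, (H, 4 * H)))
        self.wr_b = parameter(np.zeros(4 * H))
        self.out_b = parameter(np.zeros(V))
        # READER LSTM + fully-connected head to the latent space
        self.rd_Wx = parameter(_he(rng, E, (E, 4 * H)))
        self.rd_Wh = parameter(_he(rng, H, (H, 4 * H)))
        self.rd_b = parameter(np.zeros(4 * H))
        self.z_W = parameter(_he(rng, H, (H, L)))
        self.z_b = parameter(np.zeros(L))

        self.params = [
            self.embedding,
            self.enc_W1, self.enc_b1, self.enc_W2, self.enc_b2,
            self.wr_Wx, self.wr_Wh, self.wr_b, self.out_b,
            self.rd_Wx, self.rd_Wh, self.rd_b, self.z_W, self.z_b,
        ]
        self.optimizer = Adam(self.params, lr=config.learning_rate)
        self.rng = rng

    # -- bookkeeping --------------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in self.params))

    # -- differentiable forward passes --------------------------------------

    def encode(self, X: np.ndarray) -> Tensor:
        """ENCODER: (B, 6) scene matrix -> (B, H) latent h."""
        x = Tensor(X)
        hidden = (x @ self.enc_W1 + self.enc_b1).relu()
        return hidden @ self.enc_W2 + self.enc_b2

    def _lstm_step(self, Wx, Wh, b, x_t: Tensor, h: Tensor, c: Tensor):
        H = self.config.hidden_dim
        gates = x_t @ Wx + h @ Wh + b
        i = gates.cols(0, H).sigmoid()
        f = gates.cols(H, 2 * H).sigmoid()
        g = gates.cols(2 * H, 3 * H).tanh()
        o = gates.cols(3 * H, 4 * H).sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def _pad_batch(self, labels: list[str]) -> np.ndarray:
        """Token matrix (B, L) of EOS-terminated, PAD-filled sequences."""
        seqs = [self.vocab.tokenize(l) for l in labels]
        L = max(len(s) for s in seqs)
        mat = np.full((len(seqs), L), PAD_ID, dtype=np.intp)
        for i, s in enumerate(seqs):
            mat[i, : len(s)] = s
        return mat

    def generative_loss(self, scenes: list[Scene], labels: list[str]) -> Tensor:
        """Teacher-forced token-wise cross-entropy, in nats.

        Averaged over all non-padding target tokens (EOS included).
        Decoding is primed with the PAD token as begin-of-sequence.
        """
        targets = self._pad_batch(labels)
        B, L = targets.shape
        inputs = np.concatenate(
            [np.full((B, 1), PAD_ID, dtype=np.intp), targets[:, :-1]], axis=1
        )
        mask = (targets != PAD_ID).astype(float)
        h = self.encode(encode_scenes(scenes))
        c = Tensor(np.zeros_like(h.data))
        total = None
        for t in range(L):
            x_t = self.embedding.rows(inputs[:, t])
            h, c = self._lstm_step(self.wr_Wx, self.wr_Wh, self.wr_b, x_t, h, c)
            logits = h @ self.embedding.T + self.out_b
            logp = logits.log_softmax(axis=1)
            onehot = np.zeros((B, len(self.vocab)))
            onehot[np.arange(B), targets[:, t]] = mask[:, t]
            total_t = (logp * Tensor(onehot)).sum()
            total = total_t if total is None else total + total_t
        return -total * Tensor(1.0 / mask.sum())

    def read(self, labels: list[str]) -> Tensor:
        """READER: labels -> (B, L) latent z (state at each EOS)."""
        tokens = self._pad_batch(labels)
        B, L = tokens.shape
        lengths = (tokens != PAD_ID).sum(axis=1)  # includes EOS
        h = Tensor(np.zeros((B, self.config.hidden_dim)))
        c = Tensor(np.zeros((B, self.config.hidden_dim)))
        finals: list[Tensor | None] = [None] * B
        for t in range(L):
            x_t = self.embedding.rows(tokens[:, t])
            h, c = self._lstm_step(self.rd_Wx, self.rd_Wh, self.rd_b, x_t, h, c)
            for i in np.nonzero(lengths == t + 1)[0]:
                finals[i] = h.rows([i])
        final = concat(finals, axis=0)  # (B, H), rows in batch order
        return final @ self.z_W + self.z_b

    @staticmethod
    def _normalize_rows(x: Tensor) -> Tensor:
        sq = (x * x).sum(axis=1, keepdims=True) + Tensor(1e-12)
        return x * sq.pow(-0.5)

    def contrastive_loss(
        self, scenes: list[Scene], labels: list[str], temperature: float | None = None
    ) -> Tensor:
        """Symmetric NT-Xent over in-batch distractors.

        Cosine similarities between scene latents h_i and label latents
        z_j are scaled by the temperature; both retrieval directions
        (scene->label and label->scene) are cross-entropy terms with the
        matching pair as target, and the two are averaged.
        """
        if len(scenes) < 2:
            raise ValueError("contrastive loss needs a batch of at least 2")
        if len(scenes) != len(labels):
            raise ValueError("scenes and labels must align")
        tau = self.config.contrastive_temperature if temperature is None else temperature
        Hn = self._normalize_rows(self.encode(encode_scenes(scenes)))
        Zn = self._normalize_rows(self.read(labels))
        S = (Hn @ Zn.T) * Tensor(1.0 / tau)
        B = len(scenes)
        eye = np.eye(B)
        row = -(S.log_softmax(axis=1) * Tensor(eye)).sum() * Tensor(1.0 / B)
        col = -(S.log_softmax(axis=0) * Tensor(eye)).sum() * Tensor(1.0 / B)
        return (row + col) * Tensor(0.5)

    def guessing_loss(self, label: str, candidates: list[Scene], target_index: int) -> Tensor:
        """Contrastive term for one guessing trial.

        Cross-entropy of the label's latent against the candidate scenes
        (the stored distractor set), target being the true scene.
        """
        z = self._normalize_rows(self.read([label]))
        Hc = self._normalize_rows(self.encode(encode_scenes(candidates)))
        sims = (z @ Hc.T) * Tensor(1.0 / self.config.contrastive_temperature)
        onehot = np.zeros((1, len(candidates)))
        onehot[0, target_index] = 1.0
        return -(sims.log_softmax(axis=1) * Tensor(onehot)).sum()

    # -- inference (no-gradient NumPy fast paths) ----------------------------

    def _encode_np(self, X: np.ndarray) -> np.ndarray:
        hid = np.maximum(X @ self.enc_W1.data + self.enc_b1.data, 0.0)
        return hid @ self.enc_W2.data + self.enc_b2.data

    def _lstm_step_np(self, Wx, Wh, b, x, h, c):
        H = self.config.hidden_dim
        gates = x @ Wx + h @ Wh + b
        i = 1.0 / (1.0 + np.exp(-gates[:, :H]))
        f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H :]))
        c = f * c + i * g
        return o * np.tanh(c), c

    def read_np(self, label: str) -> np.ndarray:
        tokens = self.vocab.tokenize(label)
        h = np.zeros((1, self.config.hidden_dim))
        c = np.zeros_like(h)
        for t in tokens:
            x = self.embedding.data[[t]]
            h, c = self._lstm_step_np(self.rd_Wx.data, self.rd_Wh.data, self.rd_b.data, x, h, c)
        return (h @ self.z_W.data + self.z_b.data)[0]

    def produce_batch(
        self, scenes: list[Scene], mode: str = "greedy", seed: int | None = None
    ) -> list[tuple[str, bool]]:
        """Decode labels for scenes; returns (label, fallback_flag) pairs.

        Greedy mode takes the argmax character at every step and is
        deterministic; ``sample`` draws from the softmax.  Decoding stops
        at EOS or at max_label_length.  An immediate EOS would yield an
        empty label, which has no defined edit distance; it is recorded
        as the 1-character fallback token and flagged.
        """
        rng = np.random.default_rng(seed) if mode == "sample" else None
        B = len(scenes)
        h = self._encode_np(encode_scenes(scenes))
        c = np.zeros_like(h)
        prev = np.full(B, PAD_ID, dtype=np.intp)
        done = np.zeros(B, dtype=bool)
        out: list[list[int]] = [[] for _ in range(B)]
        Et = self.embedding.data.T
        for _ in range(self.config.max_label_length):
            x = self.embedding.data[prev]
            h, c = self._lstm_step_np(self.wr_Wx.data, self.wr_Wh.data, self.wr_b.data, x, h, c)
            logits = h @ Et + self.out_b.data
            logits[:, PAD_ID] = -np.inf  # PAD is never emitted
            if mode == "greedy":
                nxt = logits.argmax(axis=1)
            elif mode == "sample":
                p = np.exp(logits - logits.max(axis=1, keepdims=True))
                p /= p.sum(axis=1, keepdims=True)
                nxt = np.array([rng.choice(len(self.vocab), p=p[i]) for i in range(B)])
            else:
                raise ValueError(f"unknown mode {mode!r}")
            for i in range(B):
                if done[i]:
                    continue
                if nxt[i] == EOS_ID:
                    done[i] = True
                else:
                    out[i].append(int(nxt[i]))
            if done.all():
                break
            prev = np.where(done, PAD_ID, nxt)
        results = []
        for ids in out:
            if ids:
                results.append((self.vocab.detokenize(ids), False))
            else:
                results.append((self.config.fallback_char, True))
        return results

    def produce(self, scene: Scene, mode: str = "greedy", seed: int | None = None) -> str:
        """Produce one label for one scene (fallback flag dropped)."""
        return self.produce_batch([scene], mode=mode, seed=seed)[0][0]

    def guess(self, label: str, candidates: list[Scene]) -> int:
        """Pick the candidate scene whose encoding is closest to READER(label).

        Closeness is cosine similarity; ties break to the lowest index.
        """
        if len(candidates) == 0:
            raise ValueError("need at least one candidate")
        z = self.read_np(label)
        Hc = self._encode_np(encode_scenes(candidates))
        zn = z / np.linalg.norm(z)
        Hn = Hc / np.linalg.norm(Hc, axis=1, keepdims=True)
        return int(np.argmax(Hn @ zn))

    # -- checkpointing -------------------------------------------------------

    _PARAM_NAMES = (
        "embedding", "enc_W1", "enc_b1", "enc_W2", "enc_b2",
        "wr_Wx", "wr_Wh", "wr_b", "out_b",
        "rd_Wx", "rd_Wh", "rd_b", "z_W", "z_b",
    )

    def save(self, path) -> None:
        """Write parameters to ``<path>.npz`` with a ``<path>.json`` config
        sidecar (optimizer state is not checkpointed)."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{n: getattr(self, n).data for n in self._PARAM_NAMES})
        path.with_suffix(".json").write_text(json.dumps(asdict(self.config), indent=1))

    @classmethod
    def load(cls, path) -> "Agent":
        import json
        from pathlib import Path

        path = Path(path)
        config = AgentConfig(**json.loads(path.with_suffix(".json").read_text()))
        agent = cls(config)
        with np.load(path.with_suffix(".npz")) as data:
            for name in cls._PARAM_NAMES:
                getattr(agent, name).data[:] = data[name]
        return agent

    # -- one optimization step ----------------------------------------------

    def step(self, loss: Tensor) -> None:
        self.optimizer.zero_grad()
        loss.backward()
        self.optimizer.step()


def init_agent(config: AgentConfig) -> Agent:
    """Construct an agent with He-initialized parameters (seeded)."""
    return Agent(config)
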