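"""The character-enhanced BiLSTM-CRF tagger.

Architecture, bottom-up: character embeddings run through a character-level
BiLSTM whose final states are concatenated with the token-embedding lookup
to form the character-enhanced token embedding; the enabled lexical feature
channels (POS one-hot, gazetteer flag, affix flag) are concatenated there
as raw, untrainable inputs; a token-level BiLSTM reads the sequence in both
directions; an affine projection produces per-tag emission scores; and a
linear-chain CRF scores whole tag paths, with scheme-invalid transitions
hard-masked by default so every decoded sequence maps back to entities.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from .crf import (
    CrfParameters,
    crf_loss,
    tag_inventory,
    transition_masks,
    viterbi_decode,
)
from .embeddings import CharVocabulary, TokenVocabulary
from .lexical_features import FeatureExtractor
from .types import BIOES, SCHEMES, TagSequence, Token

FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture and channel configuration.

    Dimensions default to NeuroNER's published configuration (token
    embeddings 100, character embeddings 25, character LSTM 25 per
    direction, token LSTM 100 per direction); they are freely overridable
    and smaller values train much faster on CPU at modest cost on easy
    corpora.
    """
    labels: List[str] = field(default_factory=list)  # entity labels, no O
    scheme: str = BIOES
    d_char: int = 25
    d_char_lstm: int = 25
    d_token: int = 100
    d_token_lstm: int = 100
    dropout_rate: float = 0.5
    use_pos: bool = True
    use_gazetteer: bool = True
    use_affixes: bool = True
    mask_invalid_transitions: bool = True
    lowercase_tokens: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("d_char", "d_char_lstm", "d_token", "d_token_lstm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tags(self) -> List[str]:
        return tag_inventory(self.labels, self.scheme)


class LSTM:
    """One-direction LSTM cell with batched masked stepping."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator,
                 prefix: str, params: Dict[str, ad.Tensor]) -> None:
        self.d_in, self.d_h = d_in, d_h
        r = np.sqrt(6.0 / (d_in + d_h))
        b = np.zeros(4 * d_h)
        b[d_h:2 * d_h] = 1.0  # forget-gate bias starts open
        self.Wx = params.setdefault(
            f"{prefix}.Wx", ad.parameter(rng.uniform(-r, r, (d_in, 4 * d_h))))
        self.Wh = params.setdefault(
            f"{prefix}.Wh", ad.parameter(rng.uniform(-r, r, (d_h, 4 * d_h))))
        self.b = params.setdefault(f"{prefix}.b", ad.parameter(b))

    def step(self, x: ad.Tensor, h: ad.Tensor, c: ad.Tensor
             ) -> Tuple[ad.Tensor, ad.Tensor]:
        H = self.d_h
        gates = x @ self.Wx + h @ self.Wh + self.b
        i = ad.sigmoid(gates[:, 0:H])
        f = ad.sigmoid(gates[:, H:2 * H])
        o = ad.sigmoid(gates[:, 2 * H:3 * H])
        g = ad.tanh(gates[:, 3 * H:4 * H])
        c_new = f * c + i * g
        h_new = o * ad.tanh(c_new)
        return h_new, c_new

    def run(self, xs: Sequence[ad.Tensor],
            mask: Optional[np.ndarray] = None,
            collect: bool = False):
        """Run over time steps ``xs`` (each (B, d_in)).

        ``mask`` is (T, B, 1) with 1 for real positions; masked steps carry
        the previous state through, so the final state is the last valid
        one.  Returns (outputs or None, final h).
        """
        B = xs[0].value.shape[0]
        h = ad.as_tensor(np.zeros((B, self.d_h)))
        c = ad.as_tensor(np.zeros((B, self.d_h)))
        outputs: List[ad.Tensor] = []
        for t, x in enumerate(xs):
            h_new, c_new = self.step(x, h, c)
            if mask is not None:
                m = mask[t]
                h = h_new * m + h * (1.0 - m)
                c = c_new * m + c * (1.0 - m)
            else:
                h, c = h_new, c_new
            if collect:
                outputs.append(h)
        return (outputs if collect else None), h


class SequenceTagger:
    """Character-enhanced BiLSTM-CRF with lexical feature channels."""

    def __init__(
        self,
        config: ModelConfig,
        token_vocab: TokenVocabulary,
        char_vocab: CharVocabulary,
        features: Optional[FeatureExtractor] = None,
        resource_paths: Optional[Dict[str, str]] = None,
    ) -> None:
        if not config.labels:
            raise ValueError("config.labels must list at least one entity label")
        self.config = config
        self.token_vocab = token_vocab
        self.char_vocab = char_vocab
        self.features = features or FeatureExtractor()
        self.resource_paths = dict(resource_paths or {})
        self.tags = config.tags
        self._tag_index = {t: i for i, t in enumerate(self.tags)}
        self.rng = np.random.default_rng(config.seed)
        self.params: Dict[str, ad.Tensor] = {}
        self._build()

    # -- construction ------------------------------------------------------
    @property
    def feature_dim(self) -> int:
        return self.features.dim

    @property
    def embedding_dim(self) -> int:
        """Width of the character-enhanced token embedding after feature
        concatenation: d_token + 2 d_char_lstm + enabled feature widths."""
        return (self.config.d_token + 2 * self.config.d_char_lstm
                + self.feature_dim)

    def _build(self) -> None:
        cfg, rng, P = self.config, self.rng, self.params
        P["tok_emb"] = ad.parameter(
            np.asarray(self.token_vocab.matrix, dtype=np.float64))
        r = np.sqrt(3.0 / cfg.d_char)
        P["char_emb"] = ad.parameter(
            rng.uniform(-r, r, (self.char_vocab.size, cfg.d_char)))
        self.char_fwd = LSTM(cfg.d_char, cfg.d_char_lstm, rng, "char_fwd", P)
        self.char_bwd = LSTM(cfg.d_char, cfg.d_char_lstm, rng, "char_bwd", P)
        self.tok_fwd = LSTM(self.embedding_dim, cfg.d_token_lstm, rng,
                            "tok_fwd", P)
        self.tok_bwd = LSTM(self.embedding_dim, cfg.d_token_lstm, rng,
                            "tok_bwd", P)
        L = len(self.tags)
        r = np.sqrt(6.0 / (2 * cfg.d_token_lstm + L))
        P["proj_W"] = ad.parameter(
            rng.uniform(-r, r, (2 * cfg.d_token_lstm, L)))
        P["proj_b"] = ad.parameter(np.zeros(L))
        P["crf_trans"] = ad.parameter(np.zeros((L, L)))
        P["crf_start"] = ad.parameter(np.zeros(L))
        P["crf_stop"] = ad.parameter(np.zeros(L))
        if cfg.mask_invalid_transitions:
            tm, sm, em = transition_masks(self.tags, cfg.scheme)
        else:
            tm = np.zeros((L, L)); sm = np.zeros(L); em = np.zeros(L)
        self._masks = (tm, sm, em)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0])

    def reseed_dropout(self, seed: int) -> None:
        self._dropout_rng = np.random.default_rng(seed)

    # -- forward pass ------------------------------------------------------
    def _char_encode(self, tokens: Sequence[Token]) -> ad.Tensor:
        """(n_tokens, 2 d_char_lstm): final fwd+bwd character LSTM states,
        all tokens of the sentence batched with length masking."""
        B = len(tokens)
        lengths = [len(t.surface) for t in tokens]
        T = max(lengths)
        idx = np.full((B, T), self.char_vocab.pad_index, dtype=np.intp)
        for b, tok in enumerate(tokens):
            for j, ch in enumerate(tok.surface):
                idx[b, j] = self.char_vocab.index(ch)
        mask = np.zeros((T, B, 1))
        for b, n in enumerate(lengths):
            mask[:n, b, 0] = 1.0
        emb = self.params["char_emb"]
        xs = [emb[idx[:, t]] for t in range(T)]
        _, h_fwd = self.char_fwd.run(xs, mask)
        _, h_bwd = self.char_bwd.run(xs[::-1], mask[::-1])
        return ad.concat([h_fwd, h_bwd], axis=1)

    def _encode_padded(
        self, seqs: Sequence[Sequence[Token]], training: bool
    ) -> Tuple[ad.Tensor, List[int]]:
        """Emission scores for a batch of sentences, padded to the longest.

        Returns ((T, B, |tags|) tensor, per-sentence lengths).  Sentences
        are flattened into one token list so the character BiLSTM and the
        feature channels run once; the token BiLSTM then steps over padded
        positions with a carry-through mask, so padding never leaks into
        real states.
        """
        if not seqs or any(len(s) == 0 for s in seqs):
            raise ValueError("cannot encode an empty token sequence")
        cfg = self.config
        flat: List[Token] = [t for s in seqs for t in s]
        tok_idx = np.asarray(
            [self.token_vocab.index(t.surface) for t in flat], dtype=np.intp)
        tok_vecs = self.params["tok_emb"][tok_idx]
        char_vecs = self._char_encode(flat)
        parts = [tok_vecs, char_vecs]
        if self.feature_dim:
            parts.append(ad.as_tensor(self.features.matrix(flat)))
        embedded = ad.concat(parts, axis=1)
        embedded = ad.dropout(embedded, cfg.dropout_rate, self._dropout_rng,
                              training)
        lengths = [len(s) for s in seqs]
        B, T = len(seqs), max(lengths)
        idx = np.zeros((B, T), dtype=np.intp)  # padded -> row 0, masked out
        offset = 0
        for b, n in enumerate(lengths):
            idx[b, :n] = np.arange(offset, offset + n)
            offset += n
        mask = np.zeros((T, B, 1))
        for b, n in enumerate(lengths):
            mask[:n, b, 0] = 1.0
        xs = [embedded[idx[:, t]] for t in range(T)]
        out_f, _ = self.tok_fwd.run(xs, mask, collect=True)
        out_b, _ = self.tok_bwd.run(xs[::-1], mask[::-1], collect=True)
        hidden = ad.concat(
            [ad.stack(out_f, axis=0), ad.stack(out_b[::-1], axis=0)], axis=2)
        hidden = ad.dropout(hidden, cfg.dropout_rate, self._dropout_rng,
                            training)
        return hidden @ self.params["proj_W"] + self.params["proj_b"], lengths

    def encode(self, tokens: Sequence[Token], training: bool = False
               ) -> ad.Tensor:
        """Emission scores (n_tokens, |tags|) for one sentence."""
        padded, lengths = self._encode_padded([tokens], training)
        return padded[:, 0, :]

    def _crf_tensors(self) -> Tuple[ad.Tensor, ad.Tensor, ad.Tensor]:
        tm, sm, em = self._masks
        return (self.params["crf_trans"] + tm,
                self.params["crf_start"] + sm,
                self.params["crf_stop"] + em)

    def crf_parameters(self) -> CrfParameters:
        trans, start, stop = self._crf_tensors()
        return CrfParameters(trans.value, start.value, stop.value)

    # -- training / inference ----------------------------------------------
    def tag_ids(self, tag_seq: TagSequence) -> List[int]:
        try:
            return [self._tag_index[t] for t in tag_seq.tags]
        except KeyError as exc:
            raise ValueError(f"tag {exc.args[0]!r} outside label set") from None

    def loss(self, tokens: Sequence[Token], tag_seq: TagSequence,
             training: bool = True) -> ad.Tensor:
        emissions = self.encode(tokens, training=training)
        return crf_loss(emissions, self._crf_tensors(),
                        self.tag_ids(tag_seq))

    def batch_loss(self, batch: Sequence[Tuple[Sequence[Token], TagSequence]],
                   training: bool = True) -> ad.Tensor:
        """Summed CRF negative log-likelihood over a batch of sentences.

        The forward algorithm runs on the padded batch with a carry-through
        mask, so each sentence's partition function is read off at its own
        final position; equal to the sum of per-sentence ``crf_loss`` values.
        """
        seqs = [tokens for tokens, _ in batch]
        gold = [self.tag_ids(ts) for _, ts in batch]
        emissions, lengths = self._encode_padded(seqs, training)
        trans, start, stop = self._crf_tensors()
        B, T = len(seqs), max(lengths)
        L = len(self.tags)
        len_arr = np.asarray(lengths)
        # partition: batched forward recursion in log space
        alpha = start + emissions[0]
        for t in range(1, T):
            scores = alpha.reshape(B, L, 1) + trans
            new = ad.logsumexp(scores, axis=1) + emissions[t]
            m = (len_arr > t).astype(float).reshape(B, 1)
            alpha = new * m + alpha * (1.0 - m)
        log_z = ad.logsumexp(alpha + stop, axis=1).sum()
        # gold path scores, batched over all valid (t, b) positions
        ts_idx = np.concatenate([np.arange(n) for n in lengths])
        bs_idx = np.concatenate([np.full(n, b) for b, n in enumerate(lengths)])
        ys_idx = np.concatenate([np.asarray(g) for g in gold])
        gold_score = emissions[(ts_idx, bs_idx, ys_idx)].sum()
        gold_score = gold_score + start[[g[0] for g in gold]].sum()
        gold_score = gold_score + stop[[g[-1] for g in gold]].sum()
        prev = np.concatenate([np.asarray(g[:-1]) for g in gold if len(g) > 1])
        if prev.size:
            nxt = np.concatenate([np.asarray(g[1:]) for g in gold if len(g) > 1])
            gold_score = gold_score + trans[(prev, nxt)].sum()
        return log_z - gold_score

    def predict(self, tokens: Sequence[Token]) -> TagSequence:
        return self.predict_batch([tokens])[0]

    def predict_batch(
        self, seqs: Sequence[Sequence[Token]]
    ) -> List[TagSequence]:
        """Viterbi-decode a batch of sentences (one padded forward pass)."""
        emissions, lengths = self._encode_padded(seqs, training=False)
        crf = self.crf_parameters()
        out = []
        for b, n in enumerate(lengths):
            path, _ = viterbi_decode(emissions.value[:n, b, :], crf)
            out.append(TagSequence(self.config.scheme,
                                   [self.tags[i] for i in path]))
        return out

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        """Model directory: ``params.npz`` + ``model.json`` sidecar with
        config, tag set, vocabularies and resource SHA-256 fingerprints."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz",
                 **{k: v.value for k, v in self.params.items()})
        sidecar = {
            "format_version": FORMAT_VERSION,
            "config": asdict(self.config),
            "tags": self.tags,
            "token_vocab": {
                "tokens": self.token_vocab.tokens,
                "lowercase": self.token_vocab.lowercase,
            },
            "char_vocab": self.char_vocab.chars,
            "pos_vocab": (self.features.pos_vocab.tags
                          if self.features.pos_vocab is not None else None),
            "resources": {
                name: {"path": str(p), "sha256": _fingerprint(p)}
                for name, p in self.resource_paths.items()
            },
        }
        (directory / "model.json").write_text(
            json.dumps(sidecar, ensure_ascii=False, indent=1),
            encoding="utf-8")

    @classmethod
    def load(cls, directory, strict_resources: bool = True) -> "SequenceTagger":
        from .lexical_features import (PosVocabulary, load_affixes,
                                       load_gazetteer)
        directory = Path(directory)
        try:
            sidecar = json.loads(
                (directory / "model.json").read_text(encoding="utf-8"))
            arrays = np.load(directory / "params.npz")
        except (OSError, ValueError, json.JSONDecodeError) as exc:
            raise ValueError(f"cannot read model at {directory}: {exc}") from exc
        if sidecar.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"model format version {sidecar.get('format_version')} "
                f"!= supported {FORMAT_VERSION}")
        config = ModelConfig(**sidecar["config"])
        tv = sidecar["token_vocab"]
        token_vocab = TokenVocabulary(
            tv["tokens"], arrays["tok_emb"], tv["lowercase"])
        char_vocab = CharVocabulary(sidecar["char_vocab"])
        features = FeatureExtractor(
            pos_vocab=(PosVocabulary(sidecar["pos_vocab"])
                       if sidecar["pos_vocab"] is not None else None))
        resources = sidecar.get("resources", {})
        paths: Dict[str, str] = {}
        for name, info in resources.items():
            path = Path(info["path"])
            if not path.exists():
                if strict_resources:
                    raise ValueError(
                        f"model requires {name} file {path}, which is missing")
                continue
            if _fingerprint(path) != info["sha256"]:
                import logging
                logging.getLogger(__name__).warning(
                    "%s file %s changed since training (fingerprint mismatch)",
                    name, path)
            if name == "gazetteer":
                features.gazetteer = load_gazetteer(path)
            elif name == "affixes":
                features.affixes = load_affixes(path)
            paths[name] = str(path)
        if config.use_gazetteer and features.gazetteer is None:
            raise ValueError("config enables the gazetteer channel but no "
                             "gazetteer resource is available")
        if config.use_affixes and features.affixes is None:
            raise ValueError("config enables the affix channel but no "
                             "affix resource is available")
        model = cls(config, token_vocab, char_vocab, features, paths)
        for key in model.params:
            if key not in arrays:
                raise ValueError(f"model file is missing parameter {key}")
            if model.params[key].value.shape != arrays[key].shape:
                raise ValueError(f"parameter {key} has wrong shape")
            model.params[key].value = np.asarray(arrays[key], dtype=np.float64)
        return model


def _fingerprint(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
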