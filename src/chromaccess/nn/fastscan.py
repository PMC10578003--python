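"""Fast scoring of all single-base mutants of one sequence.

Saturation mutagenesis and greedy evolution both need model outputs for
every sequence one substitution away (3L mutants for an L-bp input).  A
naive scan re-runs the full network per mutant, but a single-base change
only perturbs the convolutional stack inside its receptive field: with
four same-padded conv layers (kernel k, pad p = k//2) interleaved with
pool-2 layers, one input column affects ≤ p+1 pooled columns after block 1
and only a handful of the final tokens.  This module re-computes exactly
those columns per mutant — gathering fixed-width windows from cached
reference activations, splicing in the previous level's recomputed values
— and then runs the (cheap) attention + head layers on the patched token
matrices.  Recomputed values follow the same arithmetic as the full
forward pass; agreement is within float32 round-off (different GEMM
shapes), and a regression test asserts closeness against the naive scan.

Only the default architecture shape is supported (pool size 2); anything
else falls back to the naive batched scan.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import layers as ly
from .model import AccessibilityNet, sigmoid


def supports_fast_scan(model: AccessibilityNet) -> bool:
    return model.config.pool_size == 2


def _block_affine(block):
    """Fold the eval-mode batch norm into scale/shift vectors."""
    bn: ly.BatchNorm1d = block[1]
    inv = 1.0 / np.sqrt(bn.running_var + bn.eps)
    scale = (bn.params["gamma"] * inv).astype(np.float32)
    shift = (bn.params["beta"] - bn.running_mean * scale).astype(np.float32)
    return scale, shift


def _valid_conv_block(block, win: np.ndarray, k: int) -> np.ndarray:
    """conv(valid) → BN(eval) → ReLU → pool2 on (M, V, C) windows."""
    conv: ly.Conv1d = block[0]
    M, V, C = win.shape
    cols = sliding_window_view(win, k, axis=1)            # (M, V-k+1, C, k)
    n = V - k + 1
    cols = cols.transpose(0, 1, 3, 2).reshape(M * n, k * C)
    y = (cols @ conv.params["W"] + conv.params["b"]).reshape(M, n, -1)
    scale, shift = _block_affine(block)
    y = y * scale + shift
    np.maximum(y, 0, out=y)
    return np.maximum(y[:, 0::2, :], y[:, 1::2, :])       # n is even by construction


def reference_activations(model: AccessibilityNet, seq_onehot: np.ndarray):
    """Forward the reference sequence, caching each conv block's input."""
    x = np.asarray(seq_onehot, dtype=np.float32)
    h = np.ascontiguousarray(x.T)[None]                   # (1, L, 4)
    acts = [h[0]]
    for block in model.conv_blocks:
        for layer in block:
            h = layer.forward(h, train=False)
        acts.append(h[0])
    return acts  # [A0 (L,4), A1, A2, A3, tokens (T, D)]


def _attention_heads(model: AccessibilityNet, tokens: np.ndarray) -> np.ndarray:
    """Positional encoding + attention + per-tissue heads on (M, T, D)."""
    h = tokens + model.pos_enc[None]
    h = model.attention.forward(h, train=False)
    flat = h.reshape(h.shape[0], -1)
    outs = []
    for tissue in model.config.tissues:
        z = flat
        for layer in model.heads[tissue]:
            z = layer.forward(z, train=False)
        outs.append(z[:, 0])
    return np.stack(outs, axis=1)


def _fc_heads(model: AccessibilityNet, ctx_joined: np.ndarray) -> np.ndarray:
    """Output projection + per-tissue heads on joined attention context."""
    att = model.attention
    out = ctx_joined @ att.params["Wo"] + att.params["bo"]
    flat = out.reshape(out.shape[0], -1)
    outs = []
    for tissue in model.config.tissues:
        z = flat
        for layer in model.heads[tissue]:
            z = layer.forward(z, train=False)
        outs.append(z[:, 0])
    return np.stack(outs, axis=1)


class _AttentionCache:
    """Reference-side quantities for incremental attention over mutants.

    With fixed per-row shifts taken from the reference scores, the exp of
    any unchanged score entry can be reused; a mutant that touches token
    rows r changes the score matrix only in rows r (fully) and columns r
    (for the other rows), so softmax sums and value-weighted numerators
    update from cached totals.
    """

    def __init__(self, model: AccessibilityNet, tokens_ref: np.ndarray):
        att = model.attention
        self.h, self.dh = att.heads, att.dh
        self.inv = 1.0 / float(np.sqrt(att.dh))
        p = att.params
        x = tokens_ref + model.pos_enc          # (T, D)
        T, D = x.shape
        self.T, self.D = T, D

        def split(m):  # (T, D) -> (h, T, dh)
            return np.ascontiguousarray(
                m.reshape(T, self.h, self.dh).transpose(1, 0, 2))

        self.q = split(x @ p["Wq"] + p["bq"])
        self.k = split(x @ p["Wk"] + p["bk"])
        self.v = split(x @ p["Wv"] + p["bv"])
        scores = self.q @ self.k.transpose(0, 2, 1) * self.inv    # (h, T, T)
        self.shift = scores.max(axis=2)                           # (h, T)
        self.E = np.exp(scores - self.shift[:, :, None])          # (h, T, T)
        self.S = self.E.sum(axis=2)                               # (h, T)
        self.N = self.E @ self.v                                  # (h, T, dh)


def _attention_heads_incremental(model: AccessibilityNet, cache: _AttentionCache,
                                 rec: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Outputs for mutants whose tokens differ from the reference only in
    rows ``starts[m] .. starts[m]+w``; exact, falls back to the dense path
    if the stable-exp guard trips."""
    att = model.attention
    p = att.params
    M, w, D = rec.shape
    h, dh, T = cache.h, cache.dh, cache.T
    ridx = starts[:, None] + np.arange(w)[None, :]                # (M, w)
    x_new = rec + model.pos_enc[ridx]                             # (M, w, D)

    def proj(name):
        z = (x_new.reshape(M * w, D) @ p["W" + name] + p["b" + name])
        return np.ascontiguousarray(
            z.reshape(M, w, h, dh).transpose(2, 0, 1, 3))         # (h, M, w, dh)

    q_new, k_new, v_new = proj("q"), proj("k"), proj("v")
    out_ctx = np.empty((M, T, h, dh), dtype=np.float32)
    for hi in range(h):
        qn, kn, vn = q_new[hi], k_new[hi], v_new[hi]              # (M, w, dh)
        # ---- recomputed rows: full score rows against the patched K
        rows = (qn.reshape(M * w, dh) @ cache.k[hi].T).reshape(M, w, T)
        qk = qn @ kn.transpose(0, 2, 1)                           # (M, w, w)
        np.put_along_axis(rows, np.broadcast_to(ridx[:, None, :], (M, w, w)),
                          qk, axis=2)
        rows *= cache.inv
        rows -= rows.max(axis=2, keepdims=True)
        np.exp(rows, out=rows)
        rows_sum = rows.sum(axis=2)                               # (M, w)
        ctx_rows = (rows.reshape(M * w, T) @ cache.v[hi]).reshape(M, w, dh)
        E_rows_r = np.take_along_axis(
            rows, np.broadcast_to(ridx[:, None, :], (M, w, w)), axis=2)
        dv = vn - cache.v[hi][ridx]                               # (M, w, dh)
        ctx_rows += E_rows_r @ dv
        ctx_rows /= rows_sum[:, :, None]
        # ---- all other rows: only columns ridx change
        cols = (kn.reshape(M * w, dh) @ cache.q[hi].T)            # (M*w, T)
        cols = cols.reshape(M, w, T).transpose(0, 2, 1) * cache.inv  # (M, T, w)
        cols -= cache.shift[hi][None, :, None]
        if cols.max() > 60.0:  # exp would lose the fixed-shift stability
            return None
        np.exp(cols, out=cols)                                    # E_new (M, T, w)
        E_old = cache.E[hi][:, ridx].transpose(1, 0, 2)           # (M, T, w)
        S_mut = cache.S[hi][None] - E_old.sum(axis=2) + cols.sum(axis=2)
        N_mut = cache.N[hi][None] - E_old @ cache.v[hi][ridx] + cols @ vn
        ctx = N_mut / S_mut[:, :, None]                           # (M, T, dh)
        np.put_along_axis(ctx, np.broadcast_to(ridx[:, :, None], (M, w, dh)),
                          ctx_rows, axis=1)
        out_ctx[:, :, hi, :] = ctx
    return _fc_heads(model, out_ctx.reshape(M, T, h * dh))


def predict_all_single_mutants(model: AccessibilityNet, seq_onehot: np.ndarray,
                               chunk: int = 768):
    """Model outputs for the reference and all 3L single-base mutants.

    Returns (p_ref (n_tissues,), p_mut (3L, n_tissues)) with mutants in
    position-major order, alternative bases ascending (reference skipped) —
    the same order the naive mutant enumeration uses.
    """
    ref = np.asarray(seq_onehot, dtype=np.uint8)
    if not supports_fast_scan(model):
        raise ValueError("fast scan requires pool size 2")
    L = ref.shape[1]
    k = model.config.kernel_size
    p = k // 2
    acts = reference_activations(model, ref)
    tokens_ref = acts[-1]
    T = tokens_ref.shape[0]
    n_blocks = len(model.conv_blocks)
    lengths = [a.shape[0] for a in acts[:-1]] + [T]

    # fixed recompute widths per level: a changed range of width W feeds a
    # conv range of width W + 2p, which pools to at most (W + 2p)//2 + 1
    # columns (the +1 absorbs odd alignment)
    widths = []
    w = 1
    for _ in range(n_blocks):
        w = (w + 2 * p) // 2 + 1
        widths.append(w)
    padded = [np.pad(a, ((p, p), (0, 0))) for a in acts[:-1]]

    ref_base = ref.argmax(axis=0)
    alts = np.array([[b for b in range(4) if b != r] for r in ref_base])  # (L, 3)
    p_ref = sigmoid(_attention_heads(model, tokens_ref[None])[0])
    cache = _AttentionCache(model, tokens_ref)

    eye = np.eye(4, dtype=np.float32)
    out = np.empty((3 * L, len(model.config.tissues)))
    for c0 in range(0, 3 * L, chunk):
        c1 = min(c0 + chunk, 3 * L)
        midx = np.arange(c0, c1)
        pos = midx // 3
        base = alts[pos, midx % 3]
        # level starts per mutant
        starts = []
        s_prev = pos  # level-0 "range" is the single changed column
        w_prev = 1
        for l in range(n_blocks):
            W = widths[l]
            s = np.clip((s_prev - p) // 2, 0, lengths[l + 1] - W)
            starts.append(s)
            s_prev, w_prev = s, W
        # level 1: gather input windows and set the mutated column
        V = 2 * widths[0] + 2 * p
        gidx = 2 * starts[0][:, None] + np.arange(V)[None, :]
        win = padded[0][gidx]                              # (M, V, 4)
        off = pos - 2 * starts[0] + p
        win[np.arange(len(pos)), off] = eye[base]
        rec = _valid_conv_block(model.conv_blocks[0], win, k)
        # levels 2..n: gather reference windows, splice previous recompute
        for l in range(1, n_blocks):
            V = 2 * widths[l] + 2 * p
            gidx = 2 * starts[l][:, None] + np.arange(V)[None, :]
            win = padded[l][gidx]                          # (M, V, C)
            off = starts[l - 1] - 2 * starts[l] + p
            sidx = off[:, None] + np.arange(widths[l - 1])[None, :]
            win[np.arange(len(pos))[:, None], sidx] = rec
            rec = _valid_conv_block(model.conv_blocks[l], win, k)
        # attention + heads on the patched tokens: incremental row/column
        # updates when the stable-exp guard allows, dense otherwise
        logits = _attention_heads_incremental(model, cache, rec, starts[-1])
        if logits is None:
            tokens = np.repeat(tokens_ref[None], len(pos), axis=0)
            tidx = starts[-1][:, None] + np.arange(widths[-1])[None, :]
            tokens[np.arange(len(pos))[:, None], tidx] = rec
            logits = _attention_heads(model, tokens)
        out[c0:c1] = sigmoid(logits)
    return p_ref, out
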