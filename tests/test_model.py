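"""Network architecture: token arithmetic, LoRA behaviour, decoder contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dzseg._autodiff import Tensor
from dzseg.errors import ConfigError, ShapeError
from dzseg.model import (Attention, DecoderConfig, Decoder, EncoderConfig,
                         LoRAConfig, TokenSequence, bilinear_matrix,
                         build_model, count_trainable_parameters, frozen_hash,
                         load_checkpoint, normalize_image, save_checkpoint)


def _small_encoder_cfg(**kw):
    base = dict(patch_size=14, embed_dim=16, num_blocks=1, num_heads=2,
                selected_stages=(1,), input_size=532)
    base.update(kw)
    return EncoderConfig(**base)


# -- patch embedding -----------------------------------------------------------

def test_token_count_follows_patch_arithmetic(tiny_model):
    enc_small = build_model(_small_encoder_cfg(), LoRAConfig(rank=0),
                            DecoderConfig(common_dim=8, num_stages=1), seed=0).encoder
    seq = enc_small.embed_patches(np.zeros((1, 532, 532, 3)))
    assert seq.tokens.shape == (1, 38 ** 2 + 1, 16)
    assert seq.num_patches == 1444
    seq28 = enc_small.embed_patches(np.zeros((1, 28, 28, 3)))
    assert seq28.num_patches == 4


def test_indivisible_input_size_raises_shape_error(tiny_model):
    with pytest.raises(ShapeError, match="530.*14|14.*530"):
        build_model(_small_encoder_cfg(), LoRAConfig(rank=0),
                    DecoderConfig(common_dim=8, num_stages=1),
                    seed=0).encoder.embed_patches(np.zeros((1, 530, 530, 3)))


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        EncoderConfig(input_size=530).validate()
    with pytest.raises(ConfigError):
        EncoderConfig(embed_dim=30, num_heads=4).validate()
    with pytest.raises(ConfigError):
        EncoderConfig(selected_stages=(13,)).validate()
    with pytest.raises(ConfigError):
        LoRAConfig(rank=2, targets=()).validate()
    with pytest.raises(ConfigError):
        DecoderConfig(num_classes=1).validate()


# -- LoRA attention -------------------------------------------------------------

def _identity_attention():
    attn = Attention(2, 1, LoRAConfig(rank=1), np.random.default_rng(0))
    for lin in (attn.q, attn.k, attn.v, attn.proj):
        lin.weight.data = np.eye(2)
        lin.bias.data = np.zeros(2)
    return attn


def test_single_token_identity_attention_returns_input():
    attn = _identity_attention()
    x = Tensor(np.array([[[0.3, -1.7]]]))
    out = attn(x)
    # one token: softmax weight is exactly 1, so output == V == input
    assert np.allclose(out.data, x.data, atol=1e-12)


def test_attention_rows_sum_to_one(tiny_model):
    attn = tiny_model.encoder.blocks[0].attn
    x = Tensor(np.random.default_rng(0).normal(size=(2, 9, 32)))
    w = attn.attention_weights(x)
    assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)


def test_zero_lora_b_matches_unadapted_attention():
    rng_in = np.random.default_rng(5)
    adapted = Attention(8, 2, LoRAConfig(rank=2), np.random.default_rng(3),
                        lora_rng=np.random.default_rng(99))
    base = Attention(8, 2, LoRAConfig(rank=0), np.random.default_rng(3))
    x = Tensor(rng_in.normal(size=(1, 6, 8)))
    assert np.allclose(adapted(x).data, base(x).data, atol=0)


def test_lora_neutrality_of_full_model(tiny_configs):
    enc, lora, dec = tiny_configs
    adapted = build_model(enc, lora, dec, seed=0)
    base = build_model(enc, LoRAConfig(rank=0), dec, seed=0)
    rng = np.random.default_rng(1)
    for _ in range(3):
        x = rng.normal(size=(1, 64, 64, 3))
        assert np.abs(adapted.forward(x).data - base.forward(x).data).max() < 1e-6


# -- stage collection ------------------------------------------------------------

def test_stage_maps_have_contracted_shape(tiny_model):
    x = np.random.default_rng(0).normal(size=(2, 64, 64, 3))
    seq = tiny_model.encoder.embed_patches(x)
    stages = tiny_model.encoder.collect_stages(seq)
    assert len(stages) == 2
    for s in stages:
        assert s.shape == (2, 32, 32, 64)  # (B, 4*sqrt(N), 4*sqrt(N), 2D)


def test_zero_class_token_zeroes_broadcast_channels(tiny_model):
    d = 32
    tokens = np.random.default_rng(0).normal(size=(1, 65, d))
    tokens[:, 0, :] = 0.0
    grid = tiny_model.encoder._stage_map(TokenSequence(Tensor(tokens)))
    assert np.abs(grid.data[..., d:]).max() == 0.0
    assert np.abs(grid.data[..., :d]).max() > 0.0


def test_upsampling_matches_naive_bilinear_oracle():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, 5, 5, 2))
    out = Tensor(x).interp2d(bilinear_matrix(20, 5), bilinear_matrix(20, 5)).data

    def naive(img, n_out):
        n_in = img.shape[0]
        res = np.zeros((n_out, n_out, img.shape[2]))
        for i in range(n_out):
            for j in range(n_out):
                si = np.clip((i + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
                sj = np.clip((j + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
                i0, j0 = int(si), int(sj)
                i1, j1 = min(i0 + 1, n_in - 1), min(j0 + 1, n_in - 1)
                fi, fj = si - i0, sj - j0
                res[i, j] = ((1 - fi) * (1 - fj) * img[i0, j0]
                             + (1 - fi) * fj * img[i0, j1]
                             + fi * (1 - fj) * img[i1, j0]
                             + fi * fj * img[i1, j1])
        return res

    assert np.allclose(out[0], naive(x[0], 20), atol=1e-12)


# -- decoder ---------------------------------------------------------------------

def test_decoder_output_shape_and_label_range(tiny_model):
    x = np.random.default_rng(0).normal(size=(1, 64, 64, 3))
    logits = tiny_model.forward(x)
    assert logits.shape == (1, 64, 64, 2)
    labels = tiny_model.predict_labels(x)
    assert set(np.unique(labels)) <= {0, 1}


def test_decoder_matches_explicit_matrix_chain():
    from scipy.special import erf
    rng = np.random.default_rng(4)
    dec = Decoder(DecoderConfig(common_dim=6, num_stages=1, num_classes=2),
                  stage_channels=4, rng=np.random.default_rng(7))
    feat = rng.normal(size=(1, 5, 5, 4))
    out = dec([Tensor(feat)], output_size=10).data

    h = feat @ dec.align[0].weight.data + dec.align[0].bias.data
    h = h @ dec.fuse.weight.data + dec.fuse.bias.data
    h = h * 0.5 * (1 + erf(h / np.sqrt(2)))
    h = h @ dec.classify.weight.data + dec.classify.bias.data
    w = bilinear_matrix(10, 5)
    expected = np.einsum("ih,jw,bhwc->bijc", w, w, h)
    assert np.allclose(out, expected, atol=1e-12)


def test_decoder_rejects_inconsistent_stages(tiny_model):
    rng = np.random.default_rng(0)
    bad = [Tensor(rng.normal(size=(1, 32, 32, 64))),
           Tensor(rng.normal(size=(1, 16, 16, 64)))]
    with pytest.raises(ShapeError):
        tiny_model.decoder(bad, output_size=64)


# -- parameter accounting and init ------------------------------------------------

def test_lora_parameter_count_closed_form():
    enc = EncoderConfig(patch_size=8, embed_dim=32, num_blocks=2, num_heads=4,
                        selected_stages=(1, 2), input_size=64)
    dec = DecoderConfig(common_dim=16, num_stages=2)
    model = build_model(enc, LoRAConfig(rank=2), dec, seed=0)
    assert count_trainable_parameters(model)["lora_params"] == 2 * 2 * (2 * 32 * 2)
    none = build_model(enc, LoRAConfig(rank=0), dec, seed=0)
    assert count_trainable_parameters(none)["lora_params"] == 0


def test_seeded_build_is_reproducible(tiny_configs):
    enc, lora, dec = tiny_configs
    x = np.random.default_rng(0).normal(size=(1, 64, 64, 3))
    a = build_model(enc, lora, dec, seed=3).forward(x).data
    b = build_model(enc, lora, dec, seed=3).forward(x).data
    assert np.array_equal(a, b)


def test_gradient_partition_frozen_vs_trainable(tiny_model):
    x = np.random.default_rng(0).normal(size=(1, 64, 64, 3))
    logits = tiny_model.forward(x)
    labels = np.random.default_rng(1).integers(0, 2, size=64 * 64)
    logits.reshape(-1, 2).cross_entropy(labels).backward()
    named = tiny_model.named_parameters()
    for name, p in named.items():
        if not p.requires_grad:
            assert p.grad is None, name
    assert any(np.abs(named[n].grad).max() > 0
               for n in named if n.endswith("lora_b"))
    assert any(np.abs(named[n].grad).max() > 0
               for n in named if n.startswith("decoder."))


# -- checkpoints -----------------------------------------------------------------

def test_checkpoint_round_trip(tmp_path, tiny_model):
    x = np.random.default_rng(0).normal(size=(1, 64, 64, 3))
    before = tiny_model.forward(x).data
    save_checkpoint(tiny_model, tmp_path / "model.npz")
    again = load_checkpoint(tmp_path / "model.npz")
    assert np.allclose(again.forward(x).data, before, atol=0)
    assert frozen_hash(again) == frozen_hash(tiny_model)


def test_checkpoint_dimension_mismatch_is_load_error(tmp_path, tiny_model, tiny_configs):
    enc, lora, dec = tiny_configs
    save_checkpoint(tiny_model, tmp_path / "model.npz")
    from dataclasses import replace
    wrong = replace(enc, embed_dim=16, num_heads=2)
    with pytest.raises(ShapeError, match="mismatch"):
        build_model(wrong, lora, dec, seed=0,
                    pretrained_checkpoint=tmp_path / "model.npz")


# -- shape conservation property ---------------------------------------------------

@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    p=st.sampled_from([4, 8]),
    grid=st.integers(2, 4),
    d=st.sampled_from([8, 16]),
    m=st.integers(1, 2),
)
def test_shapes_follow_closed_form_for_any_valid_config(p, grid, d, m):
    size = p * grid
    enc = EncoderConfig(patch_size=p, embed_dim=d, num_blocks=m, num_heads=2,
                        selected_stages=tuple(range(1, m + 1)), input_size=size)
    dec = DecoderConfig(common_dim=8, num_stages=m)
    model = build_model(enc, LoRAConfig(rank=1), dec, seed=0)
    x = np.zeros((1, size, size, 3))
    seq = model.encoder.embed_patches(x)
    assert seq.tokens.shape == (1, grid * grid + 1, d)
    stages = model.encoder.collect_stages(seq)
    assert all(s.shape == (1, 4 * grid, 4 * grid, 2 * d) for s in stages)
    assert model.forward(x).shape == (1, size, size, 2)
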