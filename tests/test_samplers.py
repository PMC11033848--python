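"""Ancestral sampling, inpainting algebra and bond reconstruction."""

import numpy as np
import pytest

import promptdiff as pd
from promptdiff.samplers import (AtomCountModel, InpaintMask,
                                 _sample_categorical_rows, inpaint_step,
                                 reconstruct_bonds)


class TestAtomCount:
    def test_point_mass(self, hbond_complex):
        graph, _ = hbond_complex
        m = AtomCountModel(bin_edges=np.array([0, np.inf]),
                           counts=np.array([20]), weights=np.array([[1.0]]))
        rng = np.random.default_rng(0)
        assert all(pd.sample_atom_count(graph, m, rng) == 20
                   for _ in range(10))

    def test_override_contract(self, hbond_complex):
        graph, _ = hbond_complex
        m = AtomCountModel.default_toy()
        rng = np.random.default_rng(0)
        assert pd.sample_atom_count(graph, m, rng, override=25) == 25

    def test_two_bin_frequencies(self, hbond_complex):
        graph, _ = hbond_complex  # pocket has < 30 atoms -> bin 0
        w = np.array([[0.3, 0.7], [1.0, 0.0]])
        m = AtomCountModel(bin_edges=np.array([0, 30, np.inf]),
                           counts=np.array([5, 9]), weights=w)
        rng = np.random.default_rng(1)
        n = 10_000
        draws = np.array([pd.sample_atom_count(graph, m, rng)
                          for _ in range(n)])
        f5 = np.mean(draws == 5)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(f5 - 0.3) < 3 * se

    def test_empty_bin_falls_back_to_marginal(self, hbond_complex, caplog):
        graph, _ = hbond_complex
        w = np.array([[0.0, 0.0], [0.5, 0.5]])
        m = AtomCountModel(bin_edges=np.array([0, 30, np.inf]),
                           counts=np.array([5, 9]), weights=w)
        with caplog.at_level("WARNING"):
            val = pd.sample_atom_count(graph, m, np.random.default_rng(0))
        assert val in (5, 9)
        assert any("marginal" in r.message for r in caplog.records)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            AtomCountModel(bin_edges=np.array([0, np.inf]),
                           counts=np.array([3]), weights=np.array([[-0.5]]))
        with pytest.raises(ValueError):
            AtomCountModel(bin_edges=np.array([0, np.inf]),
                           counts=np.array([3, 4]),
                           weights=np.array([[0.5, 0.2]]))

    def test_fit_roundtrip(self):
        m = AtomCountModel.fit([10, 10, 50, 50], [4, 4, 12, 14],
                               bin_edges=[0, 30, np.inf])
        assert m.weights[0, 4 - m.counts[0]] == 1.0
        assert np.isclose(m.weights[1].sum(), 1.0)


class TestGenerate:
    def test_deterministic_under_seed(self, hbond_complex, small_denoiser,
                                      toy_schedule):
        graph, prompts = hbond_complex
        pocket = pd.ComplexGraph(ligand=(), protein=graph.protein)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            coords, elements, _ = pd.generate_ligand(
                pocket, prompts, 3, toy_schedule, small_denoiser, rng)
            out.append((coords, elements))
        assert np.array_equal(out[0][0], out[1][0])
        assert out[0][1] == out[1][1]

    def test_one_step_perfect_denoiser(self, hbond_complex, vocab):
        """T=1 with an oracle denoiser returning the truth: output equals
        the truth exactly (beta~_1 = 0) with the true types."""
        graph, prompts = hbond_complex
        schedule = pd.make_schedule(1, "explicit", {"beta": [0.5]})
        x_true = graph.x_L - graph.x_P.mean(axis=0)
        h_true = graph.h_L(vocab)

        class Oracle:
            config = pd.DenoiserConfig(n_blocks=1, hidden=4, nheads=2,
                                       joint=False)
            vocab = pd.AtomVocabulary()

            def forward(self, x_L, h_L, x_P, h_P, v_d, t, T):
                from promptdiff.denoiser import DenoiserOutput
                from promptdiff.nn import Tensor
                B = x_L.shape[0]
                return DenoiserOutput(
                    x0_hat=Tensor(np.repeat(x_true[None], B, axis=0)),
                    h0_hat=Tensor(np.repeat(h_true[None], B, axis=0)),
                    protein_logits=Tensor(np.zeros((B, x_P.shape[1], 5))))

        pocket = pd.ComplexGraph(ligand=(), protein=graph.protein)
        coords, elements, _ = pd.generate_ligand(
            pocket, prompts, graph.n_ligand, schedule, Oracle(),
            np.random.default_rng(0))
        assert np.allclose(coords, graph.x_L, atol=1e-12)
        assert elements == graph.ligand_elements

    def test_counts_and_protein_conserved(self, hbond_complex,
                                          small_denoiser, toy_schedule):
        graph, prompts = hbond_complex
        pocket = pd.ComplexGraph(ligand=(), protein=graph.protein)
        before = pocket.x_P.copy()
        coords, elements, _ = pd.generate_ligands(
            pocket, prompts, 5, toy_schedule, small_denoiser,
            np.random.default_rng(7), n_samples=3)
        assert coords.shape == (3, 5, 3)
        assert all(len(e) == 5 for e in elements)
        assert np.array_equal(pocket.x_P, before)

    def test_unknown_prompt_residue_rejected(self, hbond_complex,
                                             small_denoiser, toy_schedule):
        graph, _ = hbond_complex
        pocket = pd.ComplexGraph(ligand=(), protein=graph.protein)
        bad = pd.InteractionPromptSet(
            (pd.PromptRecord("TRP", 42, "pi-pi", "A"),))
        with pytest.raises(ValueError):
            pd.generate_ligand(pocket, bad, 3, toy_schedule, small_denoiser,
                               np.random.default_rng(0))


class TestInpaint:
    def test_step_matches_hand_computation(self, toy_schedule):
        """Scripted Gaussians on a 2-atom system reproduce the printed
        mask combination exactly at every step."""
        rng = np.random.default_rng(5)
        x0_ref = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]])
        m = np.array([1.0, 0.0])
        x_t = rng.normal(size=(2, 3))
        for t in (1, 10, 50, 100):
            x0_hat = rng.normal(size=(2, 3))
            ek = rng.normal(size=(2, 3))
            eu = rng.normal(size=(2, 3))
            got = inpaint_step(x_t, x0_ref, x0_hat, m, t, toy_schedule, ek, eu)
            b = toy_schedule.beta_at(t)
            a = toy_schedule.alpha_at(t)
            abt = toy_schedule.alpha_bar_at(t)
            abp = toy_schedule.alpha_bar_at(t - 1)
            known = np.sqrt(1 - b) * x0_ref + np.sqrt(b) * ek
            mu = (np.sqrt(abp) * b * x0_hat + np.sqrt(a) * (1 - abp) * x_t) \
                / (1 - abt)
            unknown = mu + np.sqrt((1 - abp) / (1 - abt) * b) * eu
            expect = m[:, None] * known + (1 - m[:, None]) * unknown
            assert np.array_equal(got, expect)

    def test_masked_atoms_equal_reference_at_termination(self, hbond_complex,
                                                         toy_schedule, vocab):
        graph, _ = hbond_complex
        n = graph.n_atoms
        m = np.ones(n)
        m[0] = 0.0  # regenerate one ligand atom

        def scripted(x_t, h_t, t):
            return np.zeros((n, 3)), np.full((graph.n_ligand, vocab.K),
                                             1.0 / vocab.K)

        out = pd.inpaint(graph, InpaintMask(m), toy_schedule, scripted,
                         np.random.default_rng(3))
        ref = graph.x
        got = out.x
        fixed = m == 1.0
        assert np.allclose(got[fixed], ref[fixed], atol=0.0)
        # kept ligand atoms keep their element
        for i in range(1, graph.n_ligand):
            assert out.ligand[i].element == graph.ligand[i].element

    def test_mask_validation(self, hbond_complex, toy_schedule):
        graph, _ = hbond_complex
        with pytest.raises(ValueError):
            InpaintMask(np.array([0.5, 1.0]))
        mask = InpaintMask(np.ones(graph.n_atoms))
        with pytest.raises(ValueError, match="all-ones"):
            mask.validate_for(graph.n_atoms)
        with pytest.raises(ValueError):
            InpaintMask(np.zeros(3)).validate_for(graph.n_atoms)


class TestReconstructBonds:
    def test_single_bond_at_covalent_distance(self):
        mol = reconstruct_bonds(np.array([[0, 0, 0], [1.54, 0, 0.0]]),
                                ["C", "C"])
        assert mol.bonds == ((0, 1, "single"),)

    def test_no_bond_beyond_cutoff(self):
        mol = reconstruct_bonds(np.array([[0, 0, 0], [3.0, 0, 0.0]]),
                                ["C", "C"])
        assert mol.bonds == ()

    def test_benzene_ring_perceived_aromatic(self):
        ang = np.arange(6) * np.pi / 3
        coords = 1.39 * np.stack([np.cos(ang), np.sin(ang),
                                  np.zeros(6)], axis=1)
        mol = reconstruct_bonds(coords, ["C"] * 6)
        assert len(mol.bonds) == 6
        assert all(order == "aromatic" for _, _, order in mol.bonds)
        assert len(mol.aromatic_rings) == 1
        assert mol.aromatic_rings[0] == tuple(range(6))
        assert mol.is_valid

    def test_valence_caps_respected(self):
        # five atoms crowded around a center: fluorine accepts one bond
        center = np.zeros(3)
        shell = 1.3 * np.eye(3)
        coords = np.vstack([center, shell, [-1.3, 0, 0]])
        mol = reconstruct_bonds(coords, ["F", "C", "C", "C", "C"])
        deg0 = sum(1 for i, j, _ in mol.bonds if 0 in (i, j))
        assert deg0 == 1

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_bonds(np.zeros((1, 3)), ["Zz"])


def test_categorical_row_sampler_frequencies():
    rng = np.random.default_rng(0)
    p = np.array([[0.2, 0.8]])
    draws = np.concatenate([_sample_categorical_rows(p, rng)
                            for _ in range(5000)])
    f = draws[:, 1].mean()
    assert abs(f - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 5000)
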