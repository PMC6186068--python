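"""Shared fixtures: small toy genomes and the session-scoped trained pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromaforge import genome_tracks as gt
from chromaforge import genome_prediction as gp
from chromaforge import neural_models as nm
from chromaforge import synthetic_data as sd
from chromaforge import window_dataset as wd
from chromaforge.hic_maps import RawContactMap, distance_normalize

SEED = 1


@pytest.fixture
def toy_bins() -> gt.GenomeBins:
    sizes = pd.DataFrame({"chrom": ["chr1", "chr2"], "length": [100_000, 95_000]})
    return gt.make_bins(sizes, 10_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


class TrainedPipeline:
    """Synthetic genome, trained forward/backward models and evaluations.

    Built once per session at the study scale (N=4000 bins, M=12 factors,
    w=40, stride 2) and reused by the end-to-end and sensitivity tests.
    """

    def __init__(self) -> None:
        self.n_bins, self.n_factors, self.w, self.stride = 4000, 12, 40, 2
        self.seed = SEED
        self.truth = sd.generate_truth(self.n_bins, self.n_factors, seed=self.seed)
        self.tracks = sd.generate_tracks(self.truth)
        sizes = pd.DataFrame({"chrom": ["chrS"], "length": [self.n_bins * 10_000]})
        self.bins = gt.make_bins(sizes, 10_000)
        self.raw_map, self.norm_map = sd.generate_contact_map(self.truth, self.bins)
        samples = wd.extract_windows(
            self.tracks, self.norm_map, self.bins, w=self.w, stride=self.stride
        )
        samples = wd.mirror_augment(samples)
        bp = self.bins.bin_size
        self.split = wd.make_splits(
            samples,
            train_regions=[("chrS", 0, 3200 * bp)],
            test_regions=[("chrS", 3200 * bp, self.n_bins * bp)],
            bin_size=bp,
            val_fraction=0.2,
            seed=self.seed,
        )
        cfg = nm.TrainConfig(max_epochs=400, seed=self.seed)
        model, self.forward_history = nm.train_forward(self.split, cfg)
        ref_blocks = np.stack([s.input_block for s in self.split.train[:50]])
        self.forward_model, self.flipped = nm.orient_forward_model(model, ref_blocks, 0)
        w = self.w
        self.test = self.split.test
        self.test_outputs = [self.forward_model.predict(s.input_block) for s in self.test]
        self.test_targets = [s.target for s in self.test]
        # window targets of the noiseless generator rule, for truth-level checks
        e_true = sd.true_enrichment(self.truth, noise_sd=0)
        en = distance_normalize(
            RawContactMap(chrom_names=["chrS"], matrices={"chrS": e_true})
        ).matrices["chrS"]
        perm = wd.mirror_permutation(w)
        self.true_targets = []
        for s in self.test:
            v = wd.flatten_upper(en[s.start_bin : s.start_bin + w, s.start_bin : s.start_bin + w])
            self.true_targets.append(v[perm] if s.orientation == "inverted" else v)

        def sigma_labels(part):
            x = np.stack([s.target for s in part])
            y = np.stack(
                [self.forward_model.states(s.input_block)[w : 2 * w] for s in part]
            )
            return x, y

        xtr, ytr = sigma_labels(self.split.train)
        xva, yva = sigma_labels(self.split.validation)
        self.backward_stack, self.backward_history = nm.train_backward(
            xtr, ytr, xva, yva, cfg
        )
        self.test_inputs_bwd, self.test_sigma = sigma_labels(self.test)
        self.backward_preds = nm.dense_stack_apply(self.test_inputs_bwd, self.backward_stack)

    def bagged_vs_truth(self) -> tuple[float, float]:
        nb = {"chrS": self.n_bins}
        agg = gp.aggregate_windows(self.test_outputs, self.test, nb, kind="map")
        agg_true = gp.aggregate_windows(self.true_targets, self.test, nb, kind="map")
        bagged = gp.pearson_eval(agg.chrom_values["chrS"], agg_true.chrom_values["chrS"])
        per_window = gp.per_window_pearson(self.test_outputs, self.true_targets)
        return bagged, per_window


@pytest.fixture(scope="session")
def pipeline() -> TrainedPipeline:
    return TrainedPipeline()
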