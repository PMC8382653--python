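import numpy as np
import pytest

import multiprs as mp
from multiprs.types import VariantWeight, WeightSet, GenotypeMatrix


def tiny_config(seed=1, n=600, **overrides):
    """A fast config: 10 groups x 3 variants, small PCA panel."""
    defaults = dict(
        group_spec=tuple((g, 3) for g in mp.DEFAULT_GROUPS),
        n_pca_variants=60,
    )
    defaults.update(overrides)
    return mp.default_config(seed=seed, n_individuals=n, **defaults)


@pytest.fixture(scope="session")
def small_study():
    """One moderately sized default-config study shared across tests."""
    cfg = mp.default_config(seed=11, n_individuals=2500, n_pca_variants=400)
    return mp.simulate_study(cfg)


def toy_weightset(betas, groups=None, group="cvd", start_pos=100):
    """A WeightSet of non-ambiguous A/G variants with the given betas."""
    if groups is None:
        groups = [group] * len(betas)
    vocab = tuple(dict.fromkeys(groups))
    ws = [
        VariantWeight(f"rs{i+1}", "1", start_pos + i * 100, "A", "G", float(b), g)
        for i, (b, g) in enumerate(zip(betas, groups))
    ]
    return WeightSet(weights=ws, groups=vocab)


def toy_genotypes(dosage, weights):
    dosage = np.asarray(dosage, dtype=float)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(dosage.shape[0])],
        variant_ids=[w.variant_id for w in weights.weights],
        dosage=dosage,
        effect_allele=[w.effect_allele for w in weights.weights],
        other_allele=[w.other_allele for w in weights.weights],
        chrom=[w.chrom for w in weights.weights],
        pos=[w.pos for w in weights.weights],
    )
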