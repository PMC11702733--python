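import numpy as np
import pytest

from eprs.io_formats import (
    AncestryFrequencyPanel,
    GenotypeMatrix,
    GlobalAncestryMatrix,
    LocalAncestryTensor,
    WeightSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_weights(weights, effect="A", other="G", ids=None):
    w = np.asarray(weights, dtype=float)
    p = len(w)
    return WeightSet(
        variant_id=np.asarray(ids if ids is not None else [f"v{j+1}" for j in range(p)], dtype=object),
        effect_allele=np.asarray([effect] * p, dtype=object),
        other_allele=np.asarray([other] * p, dtype=object),
        weight=w,
    )


def make_panel(freq, ancestries=None, ids=None, counted="A"):
    freq = np.atleast_2d(np.asarray(freq, dtype=float))
    p, K = freq.shape
    return AncestryFrequencyPanel(
        variant_id=np.asarray(ids if ids is not None else [f"v{j+1}" for j in range(p)], dtype=object),
        counted_allele=np.asarray([counted] * p, dtype=object),
        ancestries=ancestries if ancestries is not None else [f"a{k+1}" for k in range(K)],
        freq=freq,
    )


def make_gam(props, ancestries=None):
    props = np.atleast_2d(np.asarray(props, dtype=float))
    n, K = props.shape
    return GlobalAncestryMatrix(
        individual_id=np.asarray([f"ind{i+1}" for i in range(n)], dtype=object),
        ancestries=ancestries if ancestries is not None else [f"a{k+1}" for k in range(K)],
        props=props,
    )


def make_lat(codes, ancestries, variant_ids=None):
    codes = np.asarray(codes)
    n, p, _ = codes.shape
    return LocalAncestryTensor(
        individual_id=np.asarray([f"ind{i+1}" for i in range(n)], dtype=object),
        variant_id=np.asarray(variant_ids if variant_ids is not None else [f"v{j+1}" for j in range(p)], dtype=object),
        ancestries=list(ancestries),
        codes=codes.astype(np.int8),
    )


def make_genotypes(dosage, ids=None, counted=None):
    dosage = np.atleast_2d(np.asarray(dosage, dtype=float))
    n, p = dosage.shape
    return GenotypeMatrix(
        individual_id=np.asarray([f"ind{i+1}" for i in range(n)], dtype=object),
        variant_id=np.asarray(ids if ids is not None else [f"v{j+1}" for j in range(p)], dtype=object),
        dosage=dosage,
        counted_allele=None if counted is None else np.asarray(counted, dtype=object),
    )
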