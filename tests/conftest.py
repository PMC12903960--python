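import numpy as np
import pytest

import plmddg as p


@pytest.fixture(scope="session")
def tiny_table(tmp_path_factory):
    """A three-row well-formed mutation table on disk, with its FASTA."""
    d = tmp_path_factory.mktemp("tiny")
    rng = np.random.default_rng(42)
    s = list(rng.choice(list(p.AMINO_ACIDS), size=150))
    s[138] = "N"  # the table below mutates N139 and F52
    s[51] = "F"
    seq = {"3OSF_A": "".join(s)}
    fasta = d / "seqs.fasta"
    with fasta.open("w") as fh:
        for k, v in seq.items():
            fh.write(f">{k}\n{v}\n")
    table = d / "mutations.tsv"
    table.write_text(
        "complex_id\tchain\twt_aa\tposition\tmut_aa\tddg\tbinding_class\tpartition\n"
        "3OSF\tA\tN\t139\tA\t2.28\tDSB\ttrain\n"
        "3OSF\tA\tF\t52\tA\t2.81\tDSB\ttrain\n"
        "3OSF\tA\tN\t139\tD\t-0.50\tDSB\ttrain\n"
    )
    return table, fasta, seq


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default synthetic benchmark: sequences, forward records, signal."""
    return p.generate()


@pytest.fixture(scope="session")
def synthetic_backends():
    """The three-channel synthetic backend set used across tests."""
    return [
        p.SyntheticBackend(64, 0),
        p.SyntheticBackend(64, 1),
        p.SyntheticBackend(48, 2),
    ]


@pytest.fixture(scope="session")
def small_model_config():
    return p.ModelConfig(
        window_length=21,
        channel_dims=(64, 64, 48),
        projected_dim=32,
        feedforward_dim=64,
    )


@pytest.fixture(scope="session")
def augmented_with_arrays(synthetic_dataset, synthetic_backends):
    """Augmented synthetic records plus their three channel arrays (L=21)."""
    seqs, records, _ = synthetic_dataset
    aug = p.reverse_augment(records)
    arrays = p.embeddings.build_channel_arrays(aug, seqs, 21, synthetic_backends)
    return seqs, aug, arrays


def brute_force_dbscan(points: np.ndarray, eps: float, min_samples: int):
    """Independent region-query DBSCAN used as a clustering oracle."""
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cid
                    stack.append(q)
        cid += 1
    return labels


def canonical_labels(labels):
    """Relabel cluster ids by first appearance so labelings compare equal."""
    mapping, out = {}, []
    for l in labels:
        if l == -1:
            out.append(-1)
            continue
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return out
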