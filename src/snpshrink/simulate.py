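"""Synthetic case/control genotype data with known planted structure.

The generator emulates the shape of population/disease SNP panels:

* *null* SNPs share one Hardy-Weinberg genotype distribution across
  classes, with the minor-allele frequency drawn once per SNP from
  Uniform(0.1, 0.5);
* *informative* SNPs are drawn from explicit per-class genotype
  distributions (the default two-class pair has a total-variation gap of
  0.35, comparable to the strongest contrasts a selected panel shows);
* missing calls are injected uniformly at a small rate;
* optional *epistatic pairs* make the labels themselves Bernoulli draws
  from a logistic model on the pair's allele dosages, so the planted
  interaction coefficient is recoverable by the epistasis test.

Every draw flows from one seed; the returned TruthManifest records what
was planted and suffices to regenerate the dataset exactly.

`table_fixture` returns machine-readable transcriptions of the published
reference tables used by the test-suite (confusion matrix, genotype
distribution vectors, per-group distributions of 20 selected SNPs, and
the interaction statistics of the reported SNP networks).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .io import MISSING, GenotypeMatrix, SNPMeta

#: default per-class genotype distributions (AA, Aa, aa) for informative
#: SNPs in a two-class design; total-variation distance 0.35
DEFAULT_INFORMATIVE_DISTS = ((0.70, 0.25, 0.05), (0.35, 0.45, 0.20))


@dataclasses.dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_per_class: int = 200
    n_classes: int = 2
    n_snps: int = 100
    n_informative: int = 5
    informative_dists: tuple = DEFAULT_INFORMATIVE_DISTS
    missing_rate: float = 0.005
    epistatic_pairs: tuple = ()   # (snp_a, snp_b, beta0, beta1, beta2, beta3)
    maf_range: tuple = (0.1, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative > self.n_snps:
            raise ValueError("n_informative exceeds n_snps")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be a proportion")
        if self.n_informative:
            dists = np.asarray(self.informative_dists, dtype=float)
            if dists.shape != (self.n_classes, 3):
                raise ValueError(
                    f"informative_dists must be {self.n_classes} x 3")
            if np.any(dists < 0) or not np.allclose(dists.sum(axis=1), 1):
                raise ValueError("informative_dists rows must be "
                                 "probability vectors")
        if self.epistatic_pairs:
            if self.n_classes != 2:
                raise ValueError("epistatic pairs need a two-class design")
            if self.n_informative:
                raise ValueError("epistatic labels are drawn from the "
                                 "logistic model; combine with "
                                 "n_informative=0")
            for pair in self.epistatic_pairs:
                a, b = int(pair[0]), int(pair[1])
                if not (0 <= a < self.n_snps and 0 <= b < self.n_snps) or a == b:
                    raise ValueError(f"bad epistatic pair indices ({a}, {b})")


@dataclasses.dataclass
class TruthManifest:
    """What was planted: enough to regenerate the dataset exactly."""

    seed: int
    informative_snps: list           # snp ids
    informative_index: list          # column indices
    class_dists: list                # per-class generating distributions
    epistatic_pairs: list            # (snp_id_a, snp_id_b, b0, b1, b2, b3)
    mafs: list                       # per-SNP minor-allele frequency (null)

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _hw_dist(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (AA, Aa, aa) at minor-allele
    frequency q."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def generate(spec: SyntheticSpec) -> tuple[GenotypeMatrix, TruthManifest]:
    """Generate a labeled genotype matrix and its truth manifest."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    K, p = spec.n_classes, spec.n_snps
    n = spec.n_per_class * K
    class_names = ([f"class{k}" for k in range(K)] if K != 2
                   else ["control", "case"])

    mafs = rng.uniform(*spec.maf_range, size=p)
    informative = np.sort(rng.choice(p, size=spec.n_informative,
                                     replace=False)) if spec.n_informative else \
        np.array([], dtype=int)
    inf_set = set(informative.tolist())

    calls = np.empty((n, p), dtype=np.int8)
    if spec.epistatic_pairs:
        # genotypes first (all null HW), then labels from the logistic model
        for j in range(p):
            calls[:, j] = rng.choice(3, size=n, p=_hw_dist(mafs[j]))
        eta = np.zeros(n)
        for (a, b, b0, b1, b2, b3) in spec.epistatic_pairs:
            g1 = calls[:, int(a)].astype(float)
            g2 = calls[:, int(b)].astype(float)
            eta += b0 + b1 * g1 + b2 * g2 + b3 * g1 * g2
        prob = 1.0 / (1.0 + np.exp(-eta))
        labels = np.where(rng.random(n) < prob, "case", "control").astype(object)
    else:
        labels = np.repeat(class_names, spec.n_per_class).astype(object)
        y = np.repeat(np.arange(K), spec.n_per_class)
        dists = (np.asarray(spec.informative_dists, dtype=float)
                 if spec.n_informative else None)
        for j in range(p):
            if j in inf_set:
                for k in range(K):
                    rows = np.flatnonzero(y == k)
                    calls[rows, j] = rng.choice(3, size=rows.size, p=dists[k])
            else:
                calls[:, j] = rng.choice(3, size=n, p=_hw_dist(mafs[j]))

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        calls[mask] = MISSING

    snps = [SNPMeta(snp_id=f"snp{j:04d}", chromosome="1", position=1000 * (j + 1),
                    alleles=("A", "G")) for j in range(p)]
    g = GenotypeMatrix(
        samples=[f"S{i + 1:04d}" for i in range(n)],
        labels=labels,
        snps=snps,
        calls=calls,
    )
    manifest = TruthManifest(
        seed=spec.seed,
        informative_snps=[snps[j].snp_id for j in informative],
        informative_index=informative.tolist(),
        class_dists=(np.asarray(spec.informative_dists, dtype=float).tolist()
                     if spec.n_informative else []),
        epistatic_pairs=[[snps[int(a)].snp_id, snps[int(b)].snp_id,
                          float(b0), float(b1), float(b2), float(b3)]
                         for (a, b, b0, b1, b2, b3) in spec.epistatic_pairs],
        mafs=mafs.tolist(),
    )
    return g, manifest


# ---------------------------------------------------------------------------
# reference-table fixtures (published values, transcribed verbatim)

_TABLE1 = {
    "classes": ["CEU", "YRI", "CHB", "JPT"],
    "counts": [[43, 0, 1, 1],
               [0, 45, 0, 0],
               [0, 0, 30, 15],
               [0, 0, 23, 22]],
    "delta": 1.5,
}

_TABLE2 = {
    "categories": ["aa", "aA", "AA"],
    "snp12": {"CEU": [0.0, 0.0667, 0.9333],
              "YRI": [0.0667, 0.5111, 0.4222],
              "CHB": [0.0, 0.0444, 0.9556],
              "JPT": [0.0, 0.0222, 0.9778]},
    "snp127": {"CEU": [0.1556, 0.4, 0.3778],
               "YRI": [0.0222, 0.1333, 0.8444],
               "CHB": [0.0, 0.0, 1.0],
               "JPT": [0.0, 0.0, 1.0]},
}

# per-group genotype distributions (AA, Aa, aa, missing) of the 20 SNPs
# selected on chromosome 14 at delta = 0.8: control group then disease group
_TABLE4 = {
    "columns": ["AA", "Aa", "aa", "missing"],
    "rows": {
        "rs12434822": ([0.4391, 0.4096, 0.1513, 0.0], [0.3000, 0.5111, 0.1889, 0.0]),
        "rs1952415": ([0.5055, 0.4354, 0.0591, 0.0], [0.6185, 0.2852, 0.0963, 0.0]),
        "rs12050360": ([0.5424, 0.3985, 0.0591, 0.0], [0.6519, 0.2889, 0.0592, 0.0]),
        "rs2248160": ([0.8155, 0.1734, 0.0111, 0.0], [0.9000, 0.1000, 0.0000, 0.0]),
        "rs7146149": ([0.4760, 0.4354, 0.0812, 0.0074], [0.6174, 0.3185, 0.0704, 0.0037]),
        "rs6573113": ([0.7232, 0.2399, 0.0369, 0.0], [0.6037, 0.3556, 0.0370, 0.0037]),
        "rs7560": ([0.6421, 0.2878, 0.0664, 0.0037], [0.5037, 0.4000, 0.0963, 0.0]),
        "rs1950902": ([0.6199, 0.3506, 0.0295, 0.0], [0.7074, 0.2519, 0.0407, 0.0]),
        "rs11626809": ([0.8044, 0.1882, 0.0074, 0.0], [0.7000, 0.2889, 0.0111, 0.0]),
        "rs1950764": ([0.7454, 0.2398, 0.0148, 0.0], [0.6370, 0.3445, 0.0185, 0.0]),
        "rs11620883": ([0.8155, 0.1808, 0.0037, 0.0], [0.9333, 0.0630, 0.0037, 0.0]),
        "rs3742837": ([0.6679, 0.3026, 0.0295, 0.0], [0.5370, 0.4222, 0.0408, 0.0]),
        "rs8006322": ([0.3653, 0.5388, 0.0959, 0.0], [0.4481, 0.3889, 0.1630, 0.0]),
        "rs12589063": ([0.3911, 0.4428, 0.1661, 0.0], [0.2445, 0.5370, 0.2037, 0.0148]),
        "rs7146193": ([0.3948, 0.4465, 0.1587, 0.0], [0.2445, 0.5481, 0.2074, 0.0]),
        "rs8016079": ([0.7048, 0.2731, 0.0221, 0.0], [0.8408, 0.1481, 0.0111, 0.0]),
        "rs12589195": ([0.6199, 0.3284, 0.0517, 0.0], [0.5148, 0.4482, 0.0370, 0.0]),
        "rs7157079": ([0.8413, 0.1550, 0.0037, 0.0], [0.9407, 0.0593, 0.0000, 0.0]),
        "rs11847484": ([0.7085, 0.2767, 0.0148, 0.0], [0.8222, 0.1704, 0.0074, 0.0]),
        "rs1152781": ([0.5978, 0.3136, 0.0886, 0.0], [0.4630, 0.4555, 0.0815, 0.0]),
    },
}

# SNP-pair interactions of the reported networks at similarity threshold
# 0.27 (all P < 0.01): (chr1, chr2, gene1, gene2, snp1, snp2, OR, chi2, P)
_TABLE6 = [
    ("1", "17", "intergenic", "KCNH6", "rs4658673", "rs4968656", 0.4873, 10.52, 0.001183),
    ("17", "17", "intergenic", "KCNH6", "rs11655589", "rs4968656", 0.5365, 10.43, 0.001242),
    ("11", "17", "intergenic", "intergenic", "rs10501570", "rs11655589", 0.5096, 8.76, 0.003083),
    ("21", "21", "ERG", "ERG", "rs2836389", "rs2836392", 0.5642, 7.55, 0.006017),
    ("8", "17", "intergenic", "intergenic", "rs10503868", "rs11655589", 0.5543, 7.49, 0.006223),
    ("14", "21", "RAD51L1", "ERG", "rs11626809", "rs2836392", 2.4410, 7.40, 0.00652),
    ("1", "17", "intergenic", "intergenic", "rs4658673", "rs11655589", 0.5534, 7.37, 0.00665),
    ("11", "17", "intergenic", "KCNH6", "rs10501570", "rs4968656", 0.5551, 6.66, 0.009844),
]


def table_fixture(name: str):
    """Published reference tables as machine-readable fixtures.

    ``table1``: 4-population confusion matrix (counts sum to 180).
    ``table2``: genotype distribution vectors of the 12th and 127th SNPs.
    ``table4``: per-group distributions of 20 selected SNPs (chromosome 14).
    ``table6``: interaction statistics (OR_int, chi2, P) of 8 SNP pairs.
    """
    fixtures = {"table1": _TABLE1, "table2": _TABLE2, "table4": _TABLE4,
                "table6": _TABLE6}
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(fixtures)}")
    import copy

    return copy.deepcopy(fixtures[name])
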