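"""Seeded multi-indication pre/post cohort simulator.

Generates a synthetic bulk-expression cohort in the package's harmonized
long format: a configurable set of tumor indications, each with a fixed
number of patients sampled once before and once after treatment, per-gene
log2 TPM values drawn from normal distributions, and every sample assigned
to one of two unmatched source databases with exact per-indication counts.

The default configuration is the package's reference fixture: 16 solid-tumor
indications with 50 pre/post pairs each (100 samples per indication), and 35
genes — the two therapeutic anchors ``"Tumor target"`` and ``"Immune
target"`` plus 33 genes partitioned into four pathway signatures. The
configured means encode the fixture's qualitative ground truth (which
indications rank above the global median for the tumor target, a
post-treatment drop in STAD, and a database batch offset in STAD), so
downstream statistics have known expected orderings to recover.

Determinism: one global seed; each indication draws from its own substream
keyed by a stable hash of its abbreviation, so adding or removing an
indication never changes another indication's values.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_SEED = 20240116
UNIT = "log2 TPM"

#: (full name, abbreviation, paired pre/post samples, database1, database2)
_INDICATIONS: tuple[tuple[str, str, int, int, int], ...] = (
    ("Bladder cancer", "BLCA", 50, 52, 48),
    ("Breast cancer", "BRCA", 50, 100, 0),
    ("Cervical cancer", "CERV", 50, 50, 50),
    ("Colorectal cancer", "CRC", 50, 62, 38),
    ("Head and neck squamous cell carcinoma", "HNSCC", 50, 50, 50),
    ("Neuroendocrine tumors", "NET", 50, 50, 50),
    ("Non-small cell lung cancer", "NSCLC", 50, 0, 100),
    ("Ovarian cancer", "OV", 50, 56, 44),
    ("Pancreatic adenocarcinoma", "PDAC", 50, 36, 64),
    ("Prostate cancer", "PRAD", 50, 44, 56),
    ("Renal cell carcinoma", "RCC", 50, 38, 62),
    ("Sarcoma", "SARC", 50, 54, 46),
    ("Small cell lung cancer", "SCLC", 50, 50, 50),
    ("Stomach adenocarcinoma", "STAD", 50, 64, 36),
    ("Triple-negative breast cancer", "TNBC", 50, 50, 50),
    ("Uterine carcinoma", "UTEN", 50, 54, 46),
)

#: Indications where the tumor target is highly expressed in the fixture.
TUMOR_TARGET_HIGH = ("CRC", "SCLC", "PRAD", "UTEN", "NET", "STAD")

_PATHWAY_PREFIXES = {
    "Pathway 1": ("TCA", 8),   # T-cell activation signature
    "Pathway 2": ("TEX", 8),   # T-cell exhaustion signature
    "Pathway 3": ("TIN", 8),   # T-cell infiltration signature
    "Pathway 4": ("NKS", 9),   # NK-cell signature
}


@dataclass(frozen=True)
class IndicationSpec:
    """One tumor-type cohort: n_pairs patients, database1+database2 == 2*n_pairs samples."""

    name: str
    abbreviation: str
    n_pairs: int
    n_database1: int
    n_database2: int


@dataclass(frozen=True)
class GeneSpec:
    """Normal-distribution parameters for one gene, per indication and treatment.

    ``pre_means`` / ``post_means`` map indication abbreviation -> mean log2
    TPM; ``sd`` is shared across indications. ``database2_shift`` optionally
    adds a batch offset (log2 units) to samples assigned to database2 in the
    listed indications, emulating a systematic source-database effect.
    """

    name: str
    sd: float
    pre_means: Mapping[str, float]
    post_means: Mapping[str, float]
    database2_shift: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimConfig:
    """Full simulator configuration; serializes to/from JSON."""

    indications: tuple[IndicationSpec, ...]
    genes: tuple[GeneSpec, ...]
    seed: int = DEFAULT_SEED
    unit: str = UNIT
    patient_id_format: str = "PT-{abbr}-{i:04d}"
    pre_suffix: str = "PRE"
    post_suffix: str = "POST"
    #: optional shared latent factor: set name -> member genes; each sample
    #: gets one N(0, latent_sd) draw per set added to all its members,
    #: inducing within-set correlation. Off (empty) by default: the reference
    #: cohort draws genes i.i.d.
    latent_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)
    latent_sd: float = 0.0

    def validate(self) -> None:
        abbrs = [i.abbreviation for i in self.indications]
        if len(set(abbrs)) != len(abbrs):
            raise ValidationError("indication abbreviations are not unique")
        for ind in self.indications:
            if ind.n_database1 + ind.n_database2 != 2 * ind.n_pairs:
                raise ValidationError(
                    f"{ind.abbreviation}: database1+database2 must equal 2*n_pairs"
                )
            if min(ind.n_pairs, ind.n_database1, ind.n_database2) < 0:
                raise ValidationError(f"{ind.abbreviation}: negative count")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("gene names are not unique")
        for g in self.genes:
            if g.sd <= 0:
                raise ValidationError(f"gene {g.name!r}: sd must be > 0")
            for abbr in abbrs:
                if abbr not in g.pre_means or abbr not in g.post_means:
                    raise ValidationError(
                        f"gene {g.name!r}: missing mean for indication {abbr!r}"
                    )

    def to_json(self, path=None) -> str:
        doc = {
            "indications": [asdict(i) for i in self.indications],
            "genes": [
                {
                    "name": g.name,
                    "sd": g.sd,
                    "pre_means": dict(g.pre_means),
                    "post_means": dict(g.post_means),
                    "database2_shift": dict(g.database2_shift),
                }
                for g in self.genes
            ],
            "seed": self.seed,
            "unit": self.unit,
            "patient_id_format": self.patient_id_format,
            "pre_suffix": self.pre_suffix,
            "post_suffix": self.post_suffix,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        known = {
            "indications", "genes", "seed", "unit",
            "patient_id_format", "pre_suffix", "post_suffix",
        }
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(
            indications=tuple(IndicationSpec(**i) for i in doc["indications"]),
            genes=tuple(
                GeneSpec(
                    name=g["name"],
                    sd=g["sd"],
                    pre_means=g["pre_means"],
                    post_means=g["post_means"],
                    database2_shift=g.get("database2_shift", {}),
                )
                for g in doc["genes"]
            ),
            seed=doc.get("seed", DEFAULT_SEED),
            unit=doc.get("unit", UNIT),
            patient_id_format=doc.get("patient_id_format", "PT-{abbr}-{i:04d}"),
            pre_suffix=doc.get("pre_suffix", "PRE"),
            post_suffix=doc.get("post_suffix", "POST"),
        )
        cfg.validate()
        return cfg


def _gene(name, sd, base_pre, base_post=None, pre=None, post=None, db2=None):
    """Build a GeneSpec from a base mean plus per-indication overrides."""
    abbrs = [i[1] for i in _INDICATIONS]
    if base_post is None:
        base_post = base_pre
    pre_means = {a: base_pre for a in abbrs}
    post_means = {a: base_post for a in abbrs}
    pre_means.update(pre or {})
    post_means.update(post or {})
    return GeneSpec(
        name=name,
        sd=sd,
        pre_means=pre_means,
        post_means=post_means,
        database2_shift=db2 or {},
    )


def default_config(seed: int = DEFAULT_SEED) -> SimConfig:
    """The reference dummy-cohort configuration.

    16 indications (50 pairs each, database splits as in the module table)
    and 35 genes. Configured orderings, used as fixture ground truth:

    * "Tumor target" means are high (6.0–6.5 log2 TPM) in CRC, SCLC, PRAD,
      UTEN, NET and STAD and low (2.5) elsewhere, so exactly those six
      indications sit above the global median threshold;
    * in STAD the "Tumor target" post-treatment mean (5.0) is below the
      pre-treatment mean (6.5);
    * in STAD, database2 samples carry a -1.5 log2 batch offset on
      "Tumor target", so database2 < database1;
    * "Immune target" is high pre-treatment in PDAC, STAD and CRC (and
      post-treatment in CRC), giving those cohorts a high high/high quadrant
      fraction against the tumor target;
    * pathway genes are elevated in NSCLC/PDAC pre-treatment (signatures
      1–3) and in SCLC (signature 4).
    """
    indications = tuple(IndicationSpec(*row) for row in _INDICATIONS)
    high = {a: 6.0 for a in TUMOR_TARGET_HIGH}
    high["STAD"] = 6.5
    high_post = {a: 6.0 for a in TUMOR_TARGET_HIGH}
    high_post["STAD"] = 5.0

    genes = [
        _gene(
            "Tumor target", 0.8, 2.5,
            pre=high, post=high_post, db2={"STAD": -1.5},
        ),
        _gene(
            "Immune target", 0.8, 3.0,
            pre={"PDAC": 6.0, "STAD": 6.0, "CRC": 6.0},
            post={"CRC": 6.0},
        ),
    ]
    rng_free = {"Pathway 1": {}, "Pathway 2": {}, "Pathway 3": {}}
    for pathway, (prefix, count) in _PATHWAY_PREFIXES.items():
        for k in range(1, count + 1):
            if pathway in rng_free:  # T-cell signatures: hot in NSCLC/PDAC pre
                pre = {"NSCLC": 5.5, "PDAC": 5.5}
                post = {}
            else:  # NK signature: high in SCLC pre and post
                pre = {"SCLC": 5.5}
                post = {"SCLC": 5.5}
            genes.append(_gene(f"{prefix}_g{k:02d}", 1.0, 3.0, pre=pre, post=post))
    cfg = SimConfig(indications=indications, genes=tuple(genes), seed=seed)
    cfg.validate()
    return cfg


def pathway_sets() -> dict[str, list[str]]:
    """The four default signatures partitioning the 33 non-target genes."""
    return {
        pathway: [f"{prefix}_g{k:02d}" for k in range(1, count + 1)]
        for pathway, (prefix, count) in _PATHWAY_PREFIXES.items()
    }


def _indication_rng(seed: int, abbreviation: str) -> np.random.Generator:
    """Substream for one indication, stable under config edits elsewhere."""
    key = zlib.crc32(abbreviation.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def simulate(config: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort; returns a harmonized long-format table.

    Per indication: ``n_pairs`` patients, each contributing one pre- and one
    post-treatment sample; database labels are a seeded permutation of an
    exact-count label vector (the configured database1/database2 totals hold
    exactly, not just in expectation); per sample and gene, the value is an
    independent normal draw at the configured mean and sd, plus any
    configured database2 batch offset. The same seed yields byte-identical
    output.
    """
    if config is None:
        config = default_config()
    config.validate()
    if seed is None:
        seed = config.seed

    frames: list[pd.DataFrame] = []
    for ind in config.indications:
        rng = _indication_rng(seed, ind.abbreviation)
        n = ind.n_pairs
        patients = [
            config.patient_id_format.format(abbr=ind.abbreviation, i=i + 1)
            for i in range(n)
        ]
        # sample order: patient-major, pre then post
        sample_ids, patient_ids, treatment = [], [], []
        for p in patients:
            sample_ids += [f"{p}-{config.pre_suffix}", f"{p}-{config.post_suffix}"]
            patient_ids += [p, p]
            treatment += ["pre", "post"]
        labels = np.array(
            ["database1"] * ind.n_database1 + ["database2"] * ind.n_database2
        )
        database = rng.permutation(labels)
        is_db2 = database == "database2"
        is_post = np.array(treatment) == "post"

        n_samples = 2 * n
        gene_latent: dict[str, np.ndarray] = {}
        if config.latent_sets and config.latent_sd > 0:
            for set_name, members in config.latent_sets.items():
                draw = rng.normal(0.0, config.latent_sd, n_samples)
                for m in members:
                    gene_latent[m] = draw
        values = np.empty((n_samples, len(config.genes)))
        for j, gene in enumerate(config.genes):
            means = np.where(
                is_post,
                gene.post_means[ind.abbreviation],
                gene.pre_means[ind.abbreviation],
            ).astype(float)
            shift = gene.database2_shift.get(ind.abbreviation, 0.0)
            if shift:
                means = means + np.where(is_db2, shift, 0.0)
            values[:, j] = rng.normal(means, gene.sd)
            if gene.name in gene_latent:
                values[:, j] += gene_latent[gene.name]

        frame = pd.DataFrame(
            {
                "patient_id": np.repeat(patient_ids, len(config.genes)),
                "sample_id": np.repeat(sample_ids, len(config.genes)),
                "feature": np.tile([g.name for g in config.genes], n_samples),
                "value": values.ravel(),
                "unit": config.unit,
                "indication": ind.abbreviation,
                "treatment": np.repeat(treatment, len(config.genes)),
                "database": np.repeat(database, len(config.genes)),
            }
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
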