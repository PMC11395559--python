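"""End-to-end pipeline runs: config validation, seed tree, run manifests.

A run executes the declared stages in dependency order — synthesize a
genome, sample sub-sequences, pretrain the reference model, fine-tune and
evaluate the probing tasks, train/extract embeddings and analyse them — and
records every output file with its SHA-256 hash in a manifest, so re-running
an identical config reproduces identical hashes (timing aside).

Every stage derives its seed deterministically from the top-level seed, and
no stage reads global RNG state.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .datasets import (
    SubsequenceSamplingScheme,
    build_masked_dataset,
    build_next_kmer_dataset,
    build_prom300_dataset,
)
from .embeddings import (
    compute_mev,
    extract_model_embeddings,
    train_word2vec_embeddings,
    umap_project,
    write_embedding_tsv,
)
from .evaluation import (
    classification_metrics,
    masked_accuracy_by_offset,
    next_kmer_accuracy,
    random_baseline,
    write_report,
)
from .models import (
    NextKmerClassifier,
    Prom300Classifier,
    ReferenceMaskedLM,
    TrainingConfig,
    save_model,
)
from .synthetic import (
    SyntheticGenomeSpec,
    SyntheticPromoterSpec,
    biased_transition_matrix,
    generate_genome,
    generate_promoters,
)
from .tokenization import build_vocabulary, write_fasta


class ConfigError(ValueError):
    """Configuration does not validate; message lists every failing key."""


class DependencyError(RuntimeError):
    """A stage requires an artifact an earlier stage did not produce."""


_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "k", "genome", "subsequences", "reference_model", "masked",
         "next_kmer", "prom300", "word2vec", "analysis"},
    "genome": {"mode", "length", "repeat_unit", "order", "strength", "base_freqs"},
    "subsequences": {"p_full", "full_len", "min_len", "count"},
    "reference_model": {"embedding_dim", "n_layers", "n_heads", "ff_dim",
                        "context_length", "learning_rate", "batch_size", "steps"},
    "masked": {"enabled", "n_eval"},
    "next_kmer": {"enabled", "k", "max_samples", "learning_rate", "steps", "batch_size"},
    "prom300": {"enabled", "n_promoters", "n_parts", "n_shuffle", "epochs",
                "learning_rate", "batch_size"},
    "word2vec": {"enabled", "dim", "window", "epochs"},
    "analysis": {"mev", "umap", "n_neighbors", "min_dist"},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "k": 4,
    "genome": {"mode": "periodic", "length": 400_000, "repeat_unit": "ACGTTAG"},
    "subsequences": {"p_full": 0.5, "full_len": 60, "min_len": 20, "count": 2000},
    "reference_model": {"embedding_dim": 64, "n_layers": 2, "n_heads": 2,
                        "ff_dim": 128, "context_length": 64,
                        "learning_rate": 2e-3, "batch_size": 32, "steps": 1200},
    "masked": {"enabled": True, "n_eval": 200},
    "next_kmer": {"enabled": True, "k": 4, "max_samples": 2500,
                  "learning_rate": 1e-3, "steps": 150, "batch_size": 64},
    "prom300": {"enabled": False, "n_promoters": 250, "n_parts": 20,
                "n_shuffle": 15, "epochs": 10, "learning_rate": 1e-3,
                "batch_size": 16},
    "word2vec": {"enabled": False, "dim": 64, "window": 5, "epochs": 3},
    "analysis": {"mev": True, "umap": False, "n_neighbors": 15, "min_dist": 0.1},
}


def validate_config(config: dict) -> dict:
    """Merge over defaults and validate; raises :class:`ConfigError` listing
    *all* failing keys at once."""
    errors: list[str] = []
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in _SCHEMA[""]:
            errors.append(f"unknown key {key!r}")
            continue
        if key in ("seed", "k"):
            merged[key] = value
            continue
        if not isinstance(value, dict):
            errors.append(f"{key!r} must be a mapping")
            continue
        for sub, sv in value.items():
            if sub not in _SCHEMA[key]:
                errors.append(f"unknown key {key}.{sub!r}")
            else:
                merged[key][sub] = sv
    if merged["k"] not in (4, 5, 6):
        errors.append(f"k must be 4, 5 or 6 for the canonical mask patterns, got {merged['k']}")
    nk = merged["next_kmer"]["k"]
    if nk not in (2, 3, 4, 5, 6):
        errors.append(f"next_kmer.k must be in 2..6, got {nk}")
    if merged["genome"]["mode"] not in ("iid", "markov", "periodic"):
        errors.append(f"genome.mode invalid: {merged['genome']['mode']!r}")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return merged


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config: dict
    seeds: dict[str, int]
    input_hashes: dict[str, str] = dc_field(default_factory=dict)
    outputs: dict[str, str] = dc_field(default_factory=dict)  # filename -> sha256
    timing: dict[str, float] = dc_field(default_factory=dict)
    results: dict = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "seeds": self.seeds,
                "input_hashes": self.input_hashes,
                "outputs": self.outputs,
                "timing": self.timing,
                "results": self.results,
            },
            indent=2,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seed tree below 2**31."""
    names = ("genome", "subsequences", "masked", "reference_model",
             "next_kmer", "prom300", "word2vec", "holdout")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages and write outputs + manifest to
    ``out_dir``.  Returns the manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    manifest = RunManifest(version=__version__, config=cfg, seeds=seeds)
    k = cfg["k"]
    vocab = build_vocabulary(k)

    def record(name: str, path: Path) -> None:
        manifest.outputs[name] = _sha256(path)

    def timed(name: str, fn):
        t0 = time.perf_counter()
        result = fn()
        manifest.timing[name] = round(time.perf_counter() - t0, 3)
        return result

    # --- genome -----------------------------------------------------------
    g = cfg["genome"]
    spec = SyntheticGenomeSpec(
        mode=g["mode"],
        length=g["length"],
        seed=seeds["genome"],
        repeat_unit=g.get("repeat_unit", "ACGT"),
        order=g.get("order", 1),
        transition=(
            biased_transition_matrix(g.get("order", 1), g.get("strength", 0.85))
            if g["mode"] == "markov"
            else None
        ),
        base_freqs=tuple(g.get("base_freqs", (0.25, 0.25, 0.25, 0.25))),
    )
    genome = timed("genome", lambda: generate_genome(spec))
    genome_path = out / "genome.fasta"
    write_fasta(genome_path, [genome])
    record("genome.fasta", genome_path)

    # --- sub-sequences and reference model --------------------------------
    sub = cfg["subsequences"]
    scheme = SubsequenceSamplingScheme(
        p_full=sub["p_full"], full_len=sub["full_len"], min_len=sub["min_len"],
        seed=seeds["subsequences"],
    )
    from .datasets import sample_subsequences  # local to keep import graph flat

    subseqs = timed(
        "subsequences", lambda: sample_subsequences([genome], scheme, k=k, count=sub["count"])
    )
    rm = cfg["reference_model"]
    model = ReferenceMaskedLM(
        k=k,
        embedding_dim=rm["embedding_dim"],
        n_layers=rm["n_layers"],
        n_heads=rm["n_heads"],
        ff_dim=rm["ff_dim"],
        context_length=rm["context_length"],
        learning_rate=rm["learning_rate"],
        batch_size=rm["batch_size"],
        steps=rm["steps"],
        seed=seeds["reference_model"],
    )
    n_hold = max(1, len(subseqs) // 10)
    train_subs, hold_subs = subseqs[:-n_hold], subseqs[-n_hold:]
    timed("pretrain", lambda: model.fit(train_subs))
    ckpt = out / "reference_model"
    save_model(ckpt, model)
    record("reference_model/weights.npz", ckpt / "weights.npz")
    record("reference_model/spec.json", ckpt / "spec.json")
    manifest.results["pretrain_final_loss"] = model.loss_history_[-1]

    # --- masked-token evaluation ------------------------------------------
    if cfg["masked"]["enabled"]:
        def run_masked():
            samples = build_masked_dataset(
                hold_subs[: cfg["masked"]["n_eval"]], vocab, seed=seeds["masked"]
            )
            preds = model.predict_masked_many(samples)
            return masked_accuracy_by_offset(list(zip(preds, samples)))

        profile = timed("masked_eval", run_masked)
        payload = {
            "per_offset_accuracy": profile.per_offset,
            "overall_accuracy": profile.overall,
            "mean_over_samples": profile.mean_over_samples,
            "counts": profile.counts,
            "seed": seeds["masked"],
        }
        write_report(out / "masked_report.json", payload)
        record("masked_report.json", out / "masked_report.json")
        manifest.results["masked_overall_accuracy"] = profile.overall

    # --- next-k-mer -------------------------------------------------------
    if cfg["next_kmer"]["enabled"]:
        nk = cfg["next_kmer"]

        def run_nextkmer():
            ds = build_next_kmer_dataset(
                [genome], k=nk["k"], max_samples=nk["max_samples"], seed=seeds["next_kmer"]
            )
            tc = TrainingConfig(
                learning_rate=nk["learning_rate"], steps=nk["steps"],
                batch_size=nk["batch_size"], seed=seeds["next_kmer"],
            )
            clf = NextKmerClassifier(model=model, k=nk["k"], config=tc).fit_dataset(ds)
            return next_kmer_accuracy(clf, ds), len(ds.test_idx)

        acc, n_test = timed("next_kmer", run_nextkmer)
        payload = {
            "k": nk["k"],
            "test_accuracy": acc,
            "random_baseline": random_baseline(nk["k"]),
            "n_test": n_test,
            "seed": seeds["next_kmer"],
        }
        write_report(out / "next_kmer_report.json", payload)
        record("next_kmer_report.json", out / "next_kmer_report.json")
        manifest.results["next_kmer_accuracy"] = acc

    # --- Prom300 ----------------------------------------------------------
    if cfg["prom300"]["enabled"]:
        pc = cfg["prom300"]

        def run_prom300():
            proms = generate_promoters(
                SyntheticPromoterSpec(n=pc["n_promoters"], seed=seeds["prom300"])
            )
            records = build_prom300_dataset(
                proms, n_parts=pc["n_parts"], n_shuffle=pc["n_shuffle"],
                seed=seeds["prom300"],
            )
            rng = np.random.default_rng(seeds["holdout"])
            order = rng.permutation(len(records))
            n_train = int(0.8 * len(records))
            train = [records[i] for i in order[:n_train]]
            test = [records[i] for i in order[n_train:]]
            tc = TrainingConfig(
                learning_rate=pc["learning_rate"], epochs=pc["epochs"],
                batch_size=pc["batch_size"], seed=seeds["prom300"],
            )
            clf = Prom300Classifier(model=model, config=tc)
            clf.fit([r.seq for r in train], [r.label for r in train])
            pred = clf.predict([r.seq for r in test])
            true = np.array([1 if r.label == "real" else 0 for r in test])
            return classification_metrics(pred, true)

        report = timed("prom300", run_prom300)
        write_report(out / "prom300_report.json", report.to_dict() | {"seed": seeds["prom300"]})
        record("prom300_report.json", out / "prom300_report.json")
        manifest.results["prom300_f1"] = report.f1

    # --- embeddings and analyses ------------------------------------------
    model_emb = extract_model_embeddings(model, vocab)
    w2v_emb = None
    if cfg["word2vec"]["enabled"]:
        wv = cfg["word2vec"]
        w2v_emb = timed(
            "word2vec",
            lambda: train_word2vec_embeddings(
                train_subs, vocab, window=wv["window"], dim=wv["dim"],
                epochs=wv["epochs"], seed=seeds["word2vec"],
            ),
        )
        write_embedding_tsv(out / "w2v_embedding.tsv", w2v_emb)
        record("w2v_embedding.tsv", out / "w2v_embedding.tsv")
    if cfg["analysis"]["mev"]:
        mev_payload = {"mev_model": compute_mev(model_emb).mev}
        if w2v_emb is not None:
            mev_payload["mev_word2vec"] = compute_mev(w2v_emb).mev
        write_report(out / "mev_report.json", mev_payload)
        record("mev_report.json", out / "mev_report.json")
        manifest.results.update(mev_payload)
    if cfg["analysis"]["umap"]:
        proj = umap_project(
            model_emb,
            n_neighbors=cfg["analysis"]["n_neighbors"],
            min_dist=cfg["analysis"]["min_dist"],
        )
        proj.to_tsv(out / "umap_model.tsv")
        record("umap_model.tsv", out / "umap_model.tsv")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest
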