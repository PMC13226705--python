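"""Run configuration, validation and provenance capture.

A :class:`RunConfig` fully describes one experiment (command + sub-config +
seed + output directory).  Replaying a saved config in single-threaded mode
reproduces every artifact bit-for-bit; each run directory receives a
``run.json`` manifest recording the config hash, seeds and library versions
so that any artifact on disk is traceable to the configuration that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .attacks import AttackConfig
from .data import SynthesisConfig
from .defenses import LPFConfig

logger = logging.getLogger("utap")

_COMMANDS = ("synth", "attack", "defend", "detect", "probe", "report", "viz")


@dataclass
class RunConfig:
    """Serializable description of one run."""

    command: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "runs/out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"command: unknown command {self.command!r}; choose from {_COMMANDS}")
        self.validate()

    # -- schema validation happens before any compute ---------------------

    def validate(self) -> None:
        """Build the relevant sub-configs so field errors surface early."""
        p = dict(self.params)
        try:
            if self.command == "synth":
                SynthesisConfig(**{**p, "seed": self._seed()})
            elif self.command == "attack":
                kwargs = {k: v for k, v in p.items()
                          if k in AttackConfig.__dataclass_fields__}
                lpf_k = p.get("lpf_k")
                if lpf_k is not None:
                    kwargs["lpf_in_loop"] = LPFConfig(kernel_size=int(lpf_k))
                AttackConfig(**{**kwargs, "seed": self._seed()})
            elif self.command == "defend":
                LPFConfig(kernel_size=int(p["k"]))
        except (TypeError, ValueError, KeyError) as exc:
            raise ValueError(f"{self.command}: invalid configuration: {exc}") from exc

    def _seed(self) -> int:
        if self.seed is None:
            raise ValueError("seed is mandatory for stochastic commands")
        return int(self.seed)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {"command": self.command, "params": self.params,
                "seed": self.seed, "out_dir": self.out_dir, "log_level": self.log_level}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def resolve_encoder(spec_str: str):
    """Resolve an encoder reference: registry name or ``tiny[:seed]``."""
    from .encoder import ENCODER_REGISTRY, build_tiny_vit

    if spec_str in ENCODER_REGISTRY:
        return ENCODER_REGISTRY[spec_str]
    if spec_str == "tiny" or spec_str.startswith("tiny:"):
        seed = int(spec_str.split(":", 1)[1]) if ":" in spec_str else 0
        return build_tiny_vit(seed)
    raise KeyError(f"unknown encoder {spec_str!r} (registry names or 'tiny[:seed]')")


def write_run_manifest(config: RunConfig, out_dir: Path, artifacts: list[str]) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "artifacts": artifacts,
        "versions": {"utap": __version__, "numpy": np.__version__},
    }
    (out_dir / "run.json").write_text(json.dumps(manifest, indent=2, default=str))


def run(config: RunConfig, dry_run: bool = False) -> int:
    """Execute a validated run; returns a process-style exit status."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    if dry_run:
        logger.info("dry run: plan validated, nothing written")
        print(yaml.safe_dump({"plan": config.to_dict(), "hash": config.digest()}))
        return 0
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = _dispatch(config, out_dir)
    write_run_manifest(config, out_dir, artifacts)
    return 0


def _dispatch(config: RunConfig, out_dir: Path) -> list[str]:
    from . import attacks, data, defenses, evaluation

    p = dict(config.params)
    cmd = config.command
    artifacts: list[str] = []

    if cmd == "synth":
        cfg = SynthesisConfig(**{**p, "seed": config._seed()})
        patchset = data.generate_synthetic_patches(cfg)
        manifest = data.write_patchset(patchset, out_dir)
        logger.info("wrote %d patches to %s", len(patchset), manifest)
        artifacts.append(str(manifest))

    elif cmd == "attack":
        family = p.pop("family", "utap")
        dataset = data.read_patchset(p.pop("manifest"))
        enc_names = p.pop("encoder")
        if isinstance(enc_names, str):
            enc_names = [enc_names]
        encoders = [resolve_encoder(e) for e in enc_names]
        lpf_k = p.pop("lpf_k", None)
        kwargs = {k: v for k, v in p.items() if k in AttackConfig.__dataclass_fields__}
        if lpf_k is not None:
            kwargs["lpf_in_loop"] = LPFConfig(kernel_size=int(lpf_k))
        if len(enc_names) > 1:
            kwargs["pool"] = enc_names
        cfg = AttackConfig(**{**kwargs, "seed": config._seed()})
        if family == "utap":
            pert, trace = attacks.utap_train(
                dataset, encoders if len(encoders) > 1 else encoders[0], cfg
            )
            out = out_dir / "perturbation.tiff"
            data.save_perturbation(pert, out)
            trace.to_frame().to_csv(out_dir / "loss_trace.csv", index=False)
            artifacts += [str(out), str(out_dir / "loss_trace.csv")]
        elif family in ("psap", "csap", "fgsm"):
            enc = encoders[0]
            feats = evaluation.encode_patchset(enc, dataset)
            probe = evaluation.train_linear_probe(feats, dataset.labels)
            if family == "psap":
                n_images = int(p.get("n_images", 1))
                for i in range(n_images):
                    pert = attacks.psap_train(
                        dataset.images[i], int(dataset.labels[i]), enc, probe,
                        bound=cfg.epsilon_8bit,
                    )
                    out = out_dir / f"psap_{dataset.ids[i]}.tiff"
                    data.save_perturbation(pert, out)
                    artifacts.append(str(out))
            elif family == "csap":
                target = int(p["target_class"])
                sel = dataset.labels == target
                pert = attacks.csap_train(
                    dataset.images[sel], target, enc, probe,
                    bound=cfg.epsilon_8bit, seed=cfg.seed,
                )
                out = out_dir / f"csap_class{target}.tiff"
                data.save_perturbation(pert, out)
                artifacts.append(str(out))
            else:  # fgsm
                mag = float(p.get("magnitude", cfg.epsilon_8bit / 255.0))
                att = np.stack([
                    np.round(attacks.fgsm(img, int(lab), enc, probe, mag) * 255.0)
                    for img, lab in zip(dataset.images, dataset.labels)
                ]).astype(np.uint8)
                att_set = data.ImagePatchSet(att, dataset.labels,
                                             list(dataset.class_names), list(dataset.ids))
                artifacts.append(str(data.write_patchset(att_set, out_dir / "fgsm")))
        else:
            raise ValueError(f"unknown attack family {family!r}")

    elif cmd == "defend":
        cfg = LPFConfig(kernel_size=int(p["k"]))
        dataset = data.read_patchset(p["manifest"])
        filtered = np.stack([
            np.round(defenses.fourier_lpf(img, cfg)) for img in dataset.images
        ]).astype(np.uint8)
        out_set = data.ImagePatchSet(filtered, dataset.labels,
                                     list(dataset.class_names), list(dataset.ids))
        artifacts.append(str(data.write_patchset(out_set, out_dir)))
        logger.info("LPF k=%d → effective NA %.3g", cfg.kernel_size,
                    defenses.effective_na(cfg, dataset.image_size))

    elif cmd == "detect":
        action = p.get("action", "train")
        clean = data.read_patchset(p["clean_manifest"])
        attacked = data.read_patchset(p["attacked_manifest"])
        if action == "train":
            model = defenses.detector_train(
                clean, attacked, variant=p.get("variant", "light"), seed=config._seed()
            )
            out = out_dir / "detector.npz"
            model.save(out)
            artifacts.append(str(out))
        else:
            model = defenses.DetectorModel.load(p["model"])
            result = defenses.detector_eval(model, clean, attacked)
            (out_dir / "detection.json").write_text(json.dumps(result, indent=2))
            artifacts.append(str(out_dir / "detection.json"))
            print(json.dumps(result, indent=2))

    elif cmd == "probe":
        enc = resolve_encoder(p.get("encoder", "tiny:0"))
        dataset = data.read_patchset(p["manifest"])
        feats = evaluation.encode_patchset(enc, dataset)
        if p.get("action", "train") == "train":
            probe = evaluation.train_linear_probe(feats, dataset.labels,
                                                  p.get("l2_strength"))
            out = out_dir / "probe.npz"
            np.savez(out, weights=probe.weights, bias=probe.bias,
                     l2_strength=probe.l2_strength)
            acc = evaluation.evaluate_probe(probe, feats, dataset.labels)
            print(f"training accuracy: {acc:.2f}%")
            artifacts.append(str(out))
        else:
            z = np.load(p["model"])
            probe = evaluation.ProbeModel(z["weights"], z["bias"],
                                          float(z["l2_strength"]), True, 0)
            acc = evaluation.evaluate_probe(probe, feats, dataset.labels)
            print(f"accuracy: {acc:.2f}%")

    elif cmd == "report":
        test_set = data.read_patchset(p["manifest"])
        train_set = data.read_patchset(p["train_manifest"])
        enc_names = p["encoders"]
        encoders = {n: resolve_encoder(n) for n in enc_names}
        probes = {
            n: evaluation.train_linear_probe(
                evaluation.encode_patchset(e, train_set), train_set.labels)
            for n, e in encoders.items()
        }
        perturbations = {
            src: data.load_perturbation(path)
            for src, path in p["perturbations"].items()
        }
        report = evaluation.transfer_matrix(perturbations, encoders, test_set, probes)
        for name, df in (("original", report.original_acc),
                         ("attacked", report.attacked_acc), ("drop", report.drop)):
            df.to_csv(out_dir / f"transfer_{name}.csv")
            artifacts.append(str(out_dir / f"transfer_{name}.csv"))
        print(report.drop.round(2))

    elif cmd == "viz":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        kind = p.get("kind", "perturbation")
        if kind == "perturbation":
            pert = data.load_perturbation(p["perturbation"])
            vis, (counts, edges) = evaluation.render_perturbation(pert)
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            ax1.imshow(vis)
            ax1.set_axis_off()
            ax2.stairs(counts, edges)
            ax2.set_xlabel("perturbation intensity (8-bit units)")
            fig.savefig(out_dir / "perturbation.png", dpi=120)
            plt.close(fig)
            artifacts.append(str(out_dir / "perturbation.png"))
        elif kind == "heatmap":
            enc = resolve_encoder(p.get("encoder", "tiny:0"))
            dataset = data.read_patchset(p["manifest"])
            grid = evaluation.attention_heatmap(dataset.images[int(p.get("index", 0))], enc)
            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.imshow(grid.values, cmap="coolwarm", vmin=-1, vmax=1)
            fig.colorbar(im)
            fig.savefig(out_dir / "heatmap.png", dpi=120)
            plt.close(fig)
            artifacts.append(str(out_dir / "heatmap.png"))
        elif kind == "embed":
            enc = resolve_encoder(p.get("encoder", "tiny:0"))
            dataset = data.read_patchset(p["manifest"])
            feats = evaluation.encode_patchset(enc, dataset)
            coords = evaluation.project_features(
                feats, method=p.get("method", "pca"), seed=config.seed or 0)
            fig, ax = plt.subplots(figsize=(5, 4))
            sc = ax.scatter(coords[:, 0], coords[:, 1], c=dataset.labels,
                            cmap="tab10", s=8)
            fig.colorbar(sc)
            fig.savefig(out_dir / "embedding.png", dpi=120)
            plt.close(fig)
            artifacts.append(str(out_dir / "embedding.png"))
        else:
            raise ValueError(f"unknown viz kind {kind!r}")

    return artifacts
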