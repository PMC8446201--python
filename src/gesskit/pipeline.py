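"""End-to-end pipeline driver: simulate -> edit -> reml -> ebv/drp -> gwas
-> annotate, with a provenance manifest.

The configuration is a nested mapping (usually loaded from YAML) with one
block per stage; a single global seed is expanded into per-stage seeds by a
fixed counter scheme (stage index appended to the root seed sequence) so
stages are independently reproducible.  Each stage records its parameters
and the SHA-256 of every file it writes; deterministic stages reproduce
their hashes on rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from gesskit import editing, io as gio
from gesskit.annotate import map_features, read_bed, read_gff3
from gesskit.blup import deregress, reliability, solve_blup
from gesskit.gwas import FarmcpuOptions, farmcpu_scan, qc_filter
from gesskit.pedigree import write_pedigree_csv
from gesskit.reml import TraitModelSpec, derive_parameters, reml_estimate
from gesskit.simulate import SimConfig, simulate_herd, write_event_log

logger = logging.getLogger("gesskit")

STAGE_SEEDS = {"simulate": 11, "gwas": 17}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence((seed, STAGE_SEEDS.get(stage, 0))).generate_state(1)[0]
        % (2**31)
    )


def validate_config(config: dict) -> None:
    """Pre-flight checks: referenced input paths must exist."""
    for key in ("pedigree", "records", "genotypes", "genes", "qtl"):
        p = config.get("paths", {}).get(key)
        if p is not None and not Path(p).exists():
            raise PipelineError(f"configured path for {key!r} does not exist: {p}")


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns the provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    validate_config(config)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}}

    def record(stage: str, params: dict, files: list) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(f.name): _sha256(f) for f in files},
        }

    try:
        # ------------------------------------------------ simulate
        sim_cfg = dict(config.get("simulate", {}))
        sim_cfg["seed"] = _stage_seed(seed, "simulate")
        cfg = SimConfig(**{k: v for k, v in sim_cfg.items()})
        ped, bv, records, genotypes, truth = simulate_herd(cfg)
        ped_path = out / "pedigree.csv"
        rec_path = out / "records.csv"
        write_pedigree_csv(ped, ped_path)
        records.to_csv(rec_path, index=False)
        files = [ped_path, rec_path]
        if genotypes is not None:
            gio.write_plink(genotypes, str(out / "genotypes"))
            gio.write_vcf(genotypes, str(out / "genotypes.vcf"))
            files += [
                out / "genotypes.ped",
                out / "genotypes.map",
                out / "genotypes.vcf",
            ]
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(truth, indent=1))
        files.append(truth_path)
        record("simulate", {k: str(v) for k, v in sim_cfg.items()}, files)

        # ------------------------------------------------ edit
        if cfg.trait_kind == "binary":
            events = write_event_log(records, seed=_stage_seed(seed, "simulate"))
            audit: list = []
            edited = editing.edit_records(events, audit=audit)
            cr_path = out / "edited_cr.csv"
            nrr_path = out / "edited_nrr56.csv"
            edited["cr"].to_csv(cr_path, index=False)
            edited["nrr56"].to_csv(nrr_path, index=False)
            audit_path = out / "audit.log"
            audit_path.write_text(
                "\n".join(json.dumps(a, default=str) for a in audit) + "\n"
            )
            record("edit", {}, [cr_path, nrr_path, audit_path])

        # ------------------------------------------------ reml
        reml_cfg = dict(config.get("reml", {}))
        spec = TraitModelSpec(
            trait=reml_cfg.get("trait", "trait"),
            fixed_factors=reml_cfg.get(
                "fixed_factors", list(cfg.fixed_effect_levels)
            ),
        )
        vc = reml_estimate(records, spec, ped)
        derived = derive_parameters(
            vc, include_cov=bool(reml_cfg.get("include_cov", False))
        )
        vc_path = out / "vc.json"
        vc_path.write_text(
            json.dumps({"components": vc.to_dict(), "derived": derived.to_dict()},
                       indent=1)
        )
        record("reml", reml_cfg, [vc_path])

        # ------------------------------------------------ ebv / drp
        blup = solve_blup(records, spec, ped, vc)
        drp_cfg = dict(config.get("drp", {}))
        sires = sorted(set(records[spec.sire_column]))
        rel = reliability(blup, effect="u_m", animals=sires)
        ebv_tab = blup.ebv_table("u_m").set_index("animal").loc[sires].reset_index()
        ebv_tab = ebv_tab.merge(rel, on="animal")
        h2_ss, _ = (
            derived.h2_ss,
            derived.h2_d,
        )
        drp_tab = deregress(
            ebv_tab,
            ped,
            h2=max(h2_ss, 1e-4),
            c=float(drp_cfg.get("c", 0.5)),
            min_accuracy=float(drp_cfg.get("min_accuracy", 0.10)),
        )
        ebv_path = out / "ebv_gess.csv"
        drp_tab.to_csv(ebv_path, index=False)
        record("ebv_drp", drp_cfg, [ebv_path])

        # ------------------------------------------------ gwas
        gwas_paths = []
        if genotypes is not None:
            used = drp_tab[drp_tab["included"] & drp_tab["drp"].notna()]
            sample_index = {s: i for i, s in enumerate(genotypes.samples)}
            idx = [sample_index[a] for a in used["animal"] if a in sample_index]
            if len(idx) >= 30:
                sub = genotypes.subset_samples(idx)
                sub_qc, report = qc_filter(sub)
                gwas_cfg = dict(config.get("gwas", {}))
                res = farmcpu_scan(
                    sub_qc,
                    used["drp"].to_numpy(),
                    weights=used["weight"].to_numpy(),
                    options=FarmcpuOptions(
                        max_qtn=int(gwas_cfg.get("max_qtn", 10)),
                        alpha=float(gwas_cfg.get("alpha", 0.05)),
                    ),
                )
                gwas_path = out / "gwas_gess.csv"
                res.table.to_csv(gwas_path, index=False)
                diag_path = out / "gwas_diagnostics.json"
                diag_path.write_text(
                    json.dumps(
                        {
                            "lambda": res.lam,
                            "pseudo_qtns": res.pseudo_qtns,
                            "qc": report,
                            "fdr_threshold": res.fdr_threshold,
                        },
                        default=float,
                        indent=1,
                    )
                )
                gwas_paths = [gwas_path, diag_path]
                record("gwas", {}, gwas_paths)

                # ------------------------------------ annotate
                genes_path = config.get("paths", {}).get("genes")
                qtl_path = config.get("paths", {}).get("qtl")
                feats = []
                if genes_path:
                    feats.append(read_gff3(genes_path))
                if qtl_path:
                    feats.append(read_bed(qtl_path))
                if feats:
                    features = pd.concat(feats, ignore_index=True)
                    hits = res.table[res.table["significant"]]
                    mapped = map_features(
                        hits,
                        features,
                        window=int(config.get("annotate", {}).get("window", 200_000)),
                    )
                    ann_path = out / "annotation.csv"
                    mapped.to_csv(ann_path, index=False)
                    record("annotate", {"window": 200_000}, [ann_path])
            else:
                logger.warning("fewer than 30 animals usable for GWAS; stage skipped")
    except PipelineError:
        raise
    except Exception as exc:  # halt with stage-scoped context
        raise PipelineError(f"pipeline stage failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
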