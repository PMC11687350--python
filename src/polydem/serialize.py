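"""JSON (de)serialisation of fitted model sets and truth parameters."""

from __future__ import annotations

import json

import numpy as np

from .vital_rates import (RATE_KEYS, FittedVitalRate, GenotypeModelSet,
                          RecruitmentConstants, SeedCalibration)


def recruitment_to_dict(rec: RecruitmentConstants) -> dict:
    return {"germination": rec.germination,
            "seedbank_survival": rec.seedbank_survival,
            "germinant_survival": rec.germinant_survival,
            "recruit_size_mean": rec.recruit_size_mean,
            "recruit_size_sd": rec.recruit_size_sd}


def recruitment_from_dict(d: dict) -> RecruitmentConstants:
    return RecruitmentConstants(**d)


def modelset_to_dict(ms: GenotypeModelSet) -> dict:
    rates = {}
    for key in RATE_KEYS:
        fit = ms.fits[key]
        rates[key] = {
            "family": fit.family,
            "terms": list(fit.terms),
            "params": fit.params.tolist(),
            "cov": fit.cov.tolist(),
            "n": int(fit.n),
            "loglik": None if not np.isfinite(fit.loglik) else float(fit.loglik),
            "aicc": None if not np.isfinite(fit.aicc_value) else float(fit.aicc_value),
            "size_col": fit.size_col,
        }
    out = {"genotype": ms.genotype,
           "recruitment": recruitment_to_dict(ms.recruitment),
           "rates": rates}
    if ms.seed_calibration is not None:
        out["seed_calibration"] = {"slope": ms.seed_calibration.slope,
                                   "intercept": ms.seed_calibration.intercept}
    return out


def modelset_from_dict(d: dict) -> GenotypeModelSet:
    fits = {}
    for key, r in d["rates"].items():
        fits[key] = FittedVitalRate(
            key=key, family=r["family"], terms=tuple(r["terms"]),
            params=np.asarray(r["params"], float),
            cov=np.asarray(r["cov"], float), n=r.get("n", 0),
            loglik=np.nan if r.get("loglik") is None else r["loglik"],
            aicc_value=np.nan if r.get("aicc") is None else r["aicc"],
            size_col=r.get("size_col"),
        )
    cal = d.get("seed_calibration")
    return GenotypeModelSet(
        genotype=d["genotype"], fits=fits,
        recruitment=recruitment_from_dict(d["recruitment"]),
        seed_calibration=SeedCalibration(**cal) if cal else None)


def save_modelset(ms: GenotypeModelSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(modelset_to_dict(ms), fh, indent=1)


def load_modelset(path) -> GenotypeModelSet:
    with open(path, encoding="utf-8") as fh:
        return modelset_from_dict(json.load(fh))
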