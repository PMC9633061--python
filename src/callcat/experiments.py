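"""Trial-list construction, paradigm execution against a model pair, and
summary tables.

Each paradigm builds a full factorial of categories x exemplars x
conditions x repetitions (with paradigm-specific twists: block design for
SNR, 2/3-regular + 1/3-catch for the chimeric paradigm), randomized by a
seed.  Execution applies the per-trial stimulus manipulation, computes
cochleagrams and FD responses for the target/distractor ensemble pair, and
realizes the WTA decision; each model instantiation is treated as one
subject.  Stimulus and FD-response caches make repeated presentations of
the same physical stimulus cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calls import CallCorpus
from .cochleagram import Cochleagram, CochleagramParams, compute_cochleagram
from .manipulate import (
    F0_GRID_PCT,
    SEGMENT_GRID_MS,
    SNR_GRID_DB,
    TEMPO_GRID_PCT,
    ManipulationSpec,
    apply_manipulation,
    manipulate_isi,
)
from .metrics import RateSummary, dprime
from .mif import MIFSet, decide_trial, fd_response

__all__ = [
    "ParadigmSpec",
    "TrialRecord",
    "build_trial_list",
    "run_experiment",
    "summarize",
    "SESSION_SIZE",
]

SESSION_SIZE = 40

ParadigmName = Literal[
    "snr",
    "segment",
    "tempo",
    "f0",
    "reverse",
    "lowpass",
    "isi_control",
    "isi_random",
    "chimeric",
    "generalization",
]


@dataclass(frozen=True)
class ParadigmSpec:
    name: ParadigmName
    condition_values: tuple = ()
    n_exemplars_per_category: int = 8
    n_repetitions: int = 5
    design: Literal["randomized", "block"] = "randomized"
    n_sessions_per_block: int = 3  # SNR block design only
    catch_fraction: float = 1 / 3  # chimeric only
    catch_reward_rate: float = 0.5  # chimeric only

    def conditions(self) -> tuple:
        if self.condition_values:
            return self.condition_values
        defaults = {
            "snr": (float("inf"),) + tuple(SNR_GRID_DB),
            "segment": tuple(SEGMENT_GRID_MS),
            "tempo": ("natural",) + tuple(TEMPO_GRID_PCT),
            "f0": ("natural",) + tuple(F0_GRID_PCT),
            "reverse": ("natural", "reversed"),
            "lowpass": ("natural", "lowpass"),
            "isi_control": ("regular", "silent"),
            "isi_random": (0, 1, 2, 3, 4),
            "chimeric": (0, 1, 2, 3, 4),
            "generalization": ("natural",),
        }
        return defaults[self.name]


@dataclass
class TrialRecord:
    index: int
    stimulus_type: Literal["go", "nogo"]
    category: str
    exemplar_id: str
    manipulation: ManipulationSpec
    condition: object
    session_id: int = 0
    is_catch: bool = False
    catch_rewarded: bool = False
    subject_id: str = ""
    response: Literal["go", "nogo", "none"] = "none"
    outcome: Literal["hit", "miss", "FA", "CR", "catch", "error", "none"] = "none"
    evidence: float = float("nan")
    go_probability: float = float("nan")
    error: str = ""


def _manipulation_for(paradigm: str, cond) -> ManipulationSpec:
    if cond == "natural" or (paradigm == "snr" and cond == float("inf")):
        return ManipulationSpec(kind="none")
    if paradigm == "snr":
        return ManipulationSpec(kind="snr", parameter=float(cond))
    if paradigm == "segment":
        return ManipulationSpec(kind="segment", parameter=float(cond))
    if paradigm == "tempo":
        return ManipulationSpec(kind="tempo", parameter=float(cond))
    if paradigm == "f0":
        return ManipulationSpec(kind="f0", parameter=float(cond))
    if paradigm == "reverse":
        return ManipulationSpec(kind="reverse")
    if paradigm == "lowpass":
        return ManipulationSpec(kind="lowpass", parameter=3000.0)
    if paradigm == "isi_control":
        return (
            ManipulationSpec(kind="none")
            if cond == "regular"
            else ManipulationSpec(kind="isi", parameter="silent")
        )
    if paradigm == "isi_random":
        return ManipulationSpec(kind="isi", parameter="random", seed=int(cond))
    if paradigm == "chimeric":
        return ManipulationSpec(kind="isi", parameter="chimeric", seed=int(cond))
    if paradigm == "generalization":
        return ManipulationSpec(kind="none")
    raise ValueError(f"unknown paradigm {paradigm!r}")


def build_trial_list(
    spec: ParadigmSpec,
    target_category: str,
    distractor_category: str,
    seed: int = 0,
    exemplar_ids: dict[str, list[str]] | None = None,
) -> list[TrialRecord]:
    """Unexecuted randomized trial list for one Go/No-go task pair.

    ``exemplar_ids`` optionally maps category -> exemplar id list; defaults
    to ``{cat}-train-{i}`` naming (``-holdout-`` for the generalization
    paradigm).
    """
    rng = np.random.default_rng(seed)
    cats = [target_category, distractor_category]
    n_ex = spec.n_exemplars_per_category
    which = "holdout" if spec.name == "generalization" else "train"
    if exemplar_ids is None:
        exemplar_ids = {c: [f"{c}-{which}-{i}" for i in range(n_ex)] for c in cats}

    def stim_type(cat: str) -> str:
        return "go" if cat == target_category else "nogo"

    trials: list[TrialRecord] = []

    if spec.name == "chimeric":
        # regular calls on 2/3 of trials, chimeric catch trials on 1/3
        variants = spec.conditions()
        catch: list[TrialRecord] = []
        for cat in cats:
            for ex in exemplar_ids[cat]:
                for v in variants:
                    for _ in range(spec.n_repetitions):
                        catch.append(
                            TrialRecord(
                                index=-1,
                                stimulus_type=stim_type(cat),
                                category=cat,
                                exemplar_id=ex,
                                manipulation=_manipulation_for("chimeric", v),
                                condition=f"chimeric-{v}",
                                is_catch=True,
                                catch_rewarded=bool(rng.uniform() < spec.catch_reward_rate),
                            )
                        )
        n_regular = int(round(len(catch) * (1 - spec.catch_fraction) / spec.catch_fraction))
        reg_reps = n_regular // (len(cats) * n_ex)
        regular = [
            TrialRecord(
                index=-1,
                stimulus_type=stim_type(cat),
                category=cat,
                exemplar_id=ex,
                manipulation=ManipulationSpec(kind="none"),
                condition="regular",
            )
            for cat in cats
            for ex in exemplar_ids[cat]
            for _ in range(reg_reps)
        ]
        trials = regular + catch
        rng.shuffle(trials)

    elif spec.name == "snr" and spec.design == "block":
        # one SNR level per session of SESSION_SIZE trials
        levels = list(spec.conditions())
        rng.shuffle(levels)
        for level in levels:
            for _ in range(spec.n_sessions_per_block):
                cell = [
                    (cat, ex) for cat in cats for ex in exemplar_ids[cat]
                ]
                session = [cell[i % len(cell)] for i in range(SESSION_SIZE)]
                rng.shuffle(session)
                for cat, ex in session:
                    trials.append(
                        TrialRecord(
                            index=-1,
                            stimulus_type=stim_type(cat),
                            category=cat,
                            exemplar_id=ex,
                            manipulation=_manipulation_for("snr", level),
                            condition=level,
                        )
                    )
    else:
        for cat in cats:
            for ex in exemplar_ids[cat]:
                for cond in spec.conditions():
                    for _ in range(spec.n_repetitions):
                        trials.append(
                            TrialRecord(
                                index=-1,
                                stimulus_type=stim_type(cat),
                                category=cat,
                                exemplar_id=ex,
                                manipulation=_manipulation_for(spec.name, cond),
                                condition=cond,
                            )
                        )
        rng.shuffle(trials)

    for i, t in enumerate(trials):
        t.index = i
        if not (spec.name == "snr" and spec.design == "block"):
            t.session_id = i // SESSION_SIZE
        else:
            t.session_id = i // SESSION_SIZE
    return trials


def _stimulus_key(t: TrialRecord) -> tuple:
    m = t.manipulation
    return (t.exemplar_id, m.kind, m.parameter, m.seed)


def run_experiment(
    target_mifsets: Sequence[MIFSet],
    distractor_mifsets: Sequence[MIFSet],
    trial_list: Sequence[TrialRecord],
    corpus: CallCorpus,
    seed: int = 0,
    deterministic: bool = False,
    params: CochleagramParams = CochleagramParams(),
    target_category: str | None = None,
    distractor_category: str | None = None,
) -> list[TrialRecord]:
    """Execute a trial list against each (target, distractor) ensemble pair.

    Instantiation ``k`` of the two ensembles forms subject ``inst-k``, which
    runs the full trial list.  Failed manipulations mark the trial outcome
    ``error`` rather than dropping it.  Returns new records (input is not
    mutated).
    """
    if len(target_mifsets) != len(distractor_mifsets):
        raise ValueError("need matching numbers of target/distractor instantiations")
    rng = np.random.default_rng(seed)
    tcat = target_category or target_mifsets[0].category
    dcat = distractor_category or distractor_mifsets[0].category
    calls = {c.exemplar_id: c for c in corpus.calls}
    donor_pools = {
        "random": {cat: corpus.isi_values(cat) for cat in (tcat, dcat)},
        "chimeric": {tcat: corpus.isi_values(dcat), dcat: corpus.isi_values(tcat)},
    }

    stim_cache: dict[tuple, Cochleagram | Exception] = {}
    fd_cache: dict[tuple, float] = {}

    def stimulus_cochleagram(t: TrialRecord) -> Cochleagram:
        key = _stimulus_key(t)
        if key not in stim_cache:
            call = calls[t.exemplar_id]
            m = t.manipulation
            try:
                if m.kind == "isi" and m.parameter in ("random", "chimeric"):
                    donors = donor_pools[str(m.parameter)][t.category]
                    stim = manipulate_isi(
                        call, str(m.parameter), donor_isis=donors, n_variants=1, seed=m.seed
                    )[0]
                else:
                    stim = apply_manipulation(call, m)
                stim_cache[key] = compute_cochleagram(stim, params)
            except Exception as e:  # flagged on the record, not dropped
                stim_cache[key] = e
        got = stim_cache[key]
        if isinstance(got, Exception):
            raise got
        return got

    out: list[TrialRecord] = []
    for k, (tset, dset) in enumerate(zip(target_mifsets, distractor_mifsets)):
        subject = f"inst-{k + 1}"
        for t in trial_list:
            rec = replace(t)
            rec.subject_id = subject
            try:
                coch = stimulus_cochleagram(t)
            except Exception as e:
                rec.outcome, rec.error = "error", str(e)
                out.append(rec)
                continue
            skey = _stimulus_key(t)
            tkey = (k, "t", skey)
            dkey = (k, "d", skey)
            if tkey not in fd_cache:
                fd_cache[tkey] = fd_response(tset, coch)
                fd_cache[dkey] = fd_response(dset, coch)
            outcome = decide_trial(
                fd_cache[tkey], fd_cache[dkey], rng=rng, deterministic=deterministic
            )
            rec.response = outcome.response
            rec.evidence = outcome.evidence
            rec.go_probability = outcome.go_probability
            if rec.is_catch:
                rec.outcome = "catch"
            elif rec.stimulus_type == "go":
                rec.outcome = "hit" if rec.response == "go" else "miss"
            else:
                rec.outcome = "FA" if rec.response == "go" else "CR"
            out.append(rec)
    return out


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "index": r.index,
                "subject": r.subject_id,
                "session": r.session_id,
                "stimulus_type": r.stimulus_type,
                "category": r.category,
                "exemplar_id": r.exemplar_id,
                "kind": r.manipulation.kind,
                "condition": r.condition,
                "is_catch": r.is_catch,
                "catch_rewarded": r.catch_rewarded,
                "response": r.response,
                "outcome": r.outcome,
                "evidence": r.evidence,
                "go_probability": r.go_probability,
            }
        )
    return pd.DataFrame(rows)


def summarize(records: Sequence[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Pooled hit/FA rates and d' per (subject, condition).

    Catch and errored trials are excluded.  Raises if any cell lacks either
    Go or No-go trials (d' needs both).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[(~df["is_catch"]) & (df["outcome"] != "error")]
    rows = []
    for (subject, cond), grp in df.groupby(["subject", "condition"], sort=False):
        go = grp[grp["stimulus_type"] == "go"]
        nogo = grp[grp["stimulus_type"] == "nogo"]
        if len(go) == 0 or len(nogo) == 0:
            raise ValueError(
                f"condition {cond!r} for subject {subject!r} lacks Go or No-go trials"
            )
        summary = RateSummary(
            n_go_trials=len(go),
            n_nogo_trials=len(nogo),
            hits=int((go["response"] == "go").sum()),
            false_alarms=int((nogo["response"] == "go").sum()),
        )
        rows.append(
            {
                "subject": subject,
                "condition": cond,
                "n_go": summary.n_go_trials,
                "n_nogo": summary.n_nogo_trials,
                "hits": summary.hits,
                "fas": summary.false_alarms,
                "hit_rate": summary.hit_rate,
                "fa_rate": summary.fa_rate,
                "dprime": dprime(summary),
            }
        )
    return pd.DataFrame(rows)
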