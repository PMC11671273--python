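"""End-to-end laminar gamma analysis: Model / Results objects.

:class:`LaminarGammaModel` wraps one recorded (or simulated) session and a
:class:`PipelineConfig`; :meth:`LaminarGammaModel.fit` runs the full
analysis chain

    broadband -> LFP/ESA -> spline iCSD -> layer border & domains
    -> gamma band -> per-domain power hotspots -> dominant gamma
    frequency per attention condition -> attention power modulation
    -> bias-corrected phase-coherence profiles and contrasts

and returns a :class:`LaminarGammaResults` carrying every intermediate
product, a text ``summary()`` and a CSV/JSON report writer.  Sessions
with behavioral performance below 65 % keep their structural results but
skip the attention-dependent analyses (flagged in the results).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coherence, gammafreq, hotspot as hotspot_mod
from .coherence import PairKind, PhcProfile
from .gammafreq import DominantFrequency
from .hotspot import HotspotSet, detect_hotspots
from .icsd import (ForwardMatrix, ICsdParams, build_forward_matrix,
                   evoked_onset_csd, invert_spline_icsd, smooth_depth_profile)
from .laminar import (Domain, LaminarAssignment, assign_domains,
                      baseline_csd_correlation_matrix,
                      detect_polarity_inversion,
                      refine_border_from_correlation)
from .preprocess import extract_esa, extract_lfp
from .session import (Attention, CsdTrial, EsaTrial, Session, read_session,
                      window_slice)
from .spectral import (GAMMA_BAND_ESA, GAMMA_BAND_WIDE, WaveletBank,
                       build_wavelet_bank, determine_gamma_band, psd_spectrum,
                       wavelet_transform)
from .stats import StatsResult, compare_independent_groups

__all__ = [
    "PipelineConfig",
    "LaminarGammaModel",
    "LaminarGammaResults",
    "run_full_pipeline",
]

MIN_PERFORMANCE = 0.65

#: Domain pairs for the attention PhC contrast (hotspot domain first).
CONTRAST_PAIRS = ((Domain.SG, Domain.IG), (Domain.G, Domain.SG),
                  (Domain.IG, Domain.G))


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of the analysis pipeline (defaults follow the text)."""

    min_performance: float = MIN_PERFORMANCE
    gamma_band: tuple[float, float] | str = GAMMA_BAND_WIDE
    esa_band: tuple[float, float] = GAMMA_BAND_ESA
    icsd: ICsdParams = field(default_factory=ICsdParams)
    compute_phc: bool = True
    compute_phc_contrast: bool = True
    voices_per_octave: int = 8
    wavelet_fmin: float = 5.0
    wavelet_fmax: float = 160.0


class LaminarGammaModel:
    """Laminar gamma-oscillation analysis of one session.

    Parameters
    ----------
    session : Session
        Trial-structured broadband laminar recording.
    config : PipelineConfig, optional
        Analysis parameters.
    """

    def __init__(self, session: Session,
                 config: PipelineConfig | None = None) -> None:
        self.session = session
        self.config = config or PipelineConfig()
        if not session.trials:
            raise ValueError("session has no trials")

    @classmethod
    def from_directory(cls, path: str | Path,
                       config: PipelineConfig | None = None,
                       ) -> "LaminarGammaModel":
        return cls(read_session(path), config=config)

    # -- fitting ----------------------------------------------------------

    def fit(self, verbose: bool = False) -> "LaminarGammaResults":
        cfg = self.config
        session = self.session
        probe = session.probe

        def log(msg: str) -> None:
            if verbose:
                print(f"[laminargamma] {msg}")

        log("extracting LFP")
        lfp_trials = [extract_lfp(t) for t in session.trials]
        fwd = build_forward_matrix(probe, cfg.icsd)

        log("evoked onset CSD and layer border")
        evoked = evoked_onset_csd(lfp_trials, probe, cfg.icsd, fwd=fwd)
        border_initial = detect_polarity_inversion(evoked)

        log("inverting CSD per trial")
        csd_raw = [invert_spline_icsd(lfp, fwd) for lfp in lfp_trials]
        csd_trials = [smooth_depth_profile(c, cfg.icsd) for c in csd_raw]
        correct = [i for i, t in enumerate(session.trials) if t.condition.correct]
        # unsmoothed CSD keeps the correlation-block boundary sharp; the
        # spatial smoothing is applied for the power and PhC analyses
        corr = baseline_csd_correlation_matrix([csd_raw[i] for i in correct])
        border = refine_border_from_correlation(corr, border_initial, probe)
        assignment = assign_domains(border, probe, method="refined")

        bank = build_wavelet_bank(cfg.wavelet_fmin, cfg.wavelet_fmax,
                                  cfg.voices_per_octave)
        if cfg.gamma_band == "auto":
            log("determining gamma band from the mean corrected PSD")
            band = self._auto_band(csd_trials, correct, bank)
        else:
            band = tuple(cfg.gamma_band)

        log("gamma-power depth profiles")
        by_cond = {att: [i for i in correct
                         if session.trials[i].condition.attention == att]
                   for att in Attention}
        profiles = {}
        for att, idx in by_cond.items():
            if idx:
                profiles[att] = hotspot_mod.gamma_power_depth_profile(
                    [csd_trials[i] for i in idx], bank, band, window="mc23")
        baseline_profile = None
        if by_cond[Attention.ATTEND_IN]:
            baseline_profile = hotspot_mod.gamma_power_depth_profile(
                [csd_trials[i] for i in by_cond[Attention.ATTEND_IN]],
                bank, band, window="baseline")

        hotspot_source = profiles.get(Attention.ATTEND_IN)
        if hotspot_source is None:
            raise ValueError("no correct attend-in trials; cannot detect "
                             "hotspots")
        hotspots = detect_hotspots(hotspot_source, assignment,
                                   baseline_profile)

        attention_ok = session.performance >= cfg.min_performance
        conditions = (list(Attention) if attention_ok
                      else [Attention.ATTEND_IN])

        log("dominant gamma frequencies")
        # unsmoothed CSD: depth smoothing attenuates the local oscillator
        # relative to neighboring-domain leakage at the hotspot channel
        dominant = self._dominant_frequencies(csd_raw, by_cond, hotspots,
                                              conditions)
        power_mod = (self._attention_power_modulation(profiles, hotspots)
                     if attention_ok else None)
        freq_stats = self._frequency_stats(csd_raw, by_cond, hotspots)

        phc_profiles: dict[Domain, PhcProfile] = {}
        preference = None
        esa_channels: list[int] | None = None
        esa_power = None
        contrasts = None
        if cfg.compute_phc:
            log("ESA extraction and phase coherence")
            esa_trials = [extract_esa(session.trials[i])
                          for i in by_cond[Attention.ATTEND_IN]]
            csd_in = [csd_trials[i] for i in by_cond[Attention.ATTEND_IN]]
            esa_power = self._esa_gamma_power(esa_trials, bank, band)
            esa_channels = hotspot_mod.select_esa_channels(esa_power)
            phc_profiles = self._phc_esa_profiles(csd_in, esa_trials,
                                                  hotspots, bank,
                                                  esa_channels)
            preference = self._preference(phc_profiles, cfg.esa_band, probe)
            if cfg.compute_phc_contrast and attention_ok:
                csd_nearby = [csd_trials[i]
                              for i in by_cond[Attention.ATTEND_NEARBY]]
                if len(csd_nearby) >= 2:
                    contrasts = self._phc_contrasts(csd_in, csd_nearby,
                                                    hotspots, assignment,
                                                    bank, band)

        return LaminarGammaResults(
            model=self,
            gamma_band=band,
            evoked_csd=evoked,
            border_initial_um=border_initial,
            assignment=assignment,
            baseline_correlation=corr,
            power_profiles=profiles,
            baseline_power_profile=baseline_profile,
            hotspots=hotspots,
            dominant_frequency=dominant,
            attention_power_modulation=power_mod,
            frequency_stats=freq_stats,
            esa_channels=esa_channels,
            esa_gamma_power=esa_power,
            phc_esa_profiles=phc_profiles,
            phc_preference=preference,
            phc_contrasts=contrasts,
            attention_analyses_skipped=not attention_ok,
        )

    # -- stages -----------------------------------------------------------

    def _auto_band(self, csd_trials, correct, bank) -> tuple[float, float]:
        acc = None
        for i in correct:
            trial = csd_trials[i]
            sl = window_slice(trial.epochs, trial.fs, "mc23")
            tfr = wavelet_transform(trial.data, bank)
            psd = psd_spectrum(tfr, window=sl, one_over_f_correct=True)
            acc = psd if acc is None else acc + psd
        mean_psd = (acc / len(correct)).mean(axis=1)
        return determine_gamma_band(bank.f0_hz, mean_psd)

    def _dominant_frequencies(self, csd_trials, by_cond, hotspots,
                              conditions) -> pd.DataFrame:
        rows = []
        for domain in Domain:
            ch = hotspots.channel(domain)
            if ch is None:
                continue
            for att in conditions:
                series = []
                for i in by_cond[att]:
                    trial = csd_trials[i]
                    nb = gammafreq.bandpass_gamma(trial.data[ch], trial.fs)
                    phase, amp = gammafreq.analytic_phase_amplitude(nb,
                                                                    trial.fs)
                    sl = window_slice(trial.epochs, trial.fs, "mc23")
                    series.append(gammafreq.detect_gamma_troughs(phase, amp,
                                                                 sl, trial.fs))
                try:
                    dom = gammafreq.dominant_frequency_from_periods(series)
                except ValueError:
                    continue
                rows.append({"domain": domain.value, "condition": att.value,
                             "freq_hz": dom.freq_hz,
                             "median_period_s": dom.median_period_s,
                             "n_cycles": dom.n_cycles})
        return pd.DataFrame(rows)

    def _attention_power_modulation(self, profiles, hotspots) -> pd.DataFrame:
        rows = []
        away = profiles.get(Attention.ATTEND_AWAY)
        if away is None:
            return pd.DataFrame(rows)
        for domain in Domain:
            ch = hotspots.channel(domain)
            if ch is None:
                continue
            for att in (Attention.ATTEND_IN, Attention.ATTEND_NEARBY):
                prof = profiles.get(att)
                if prof is None:
                    continue
                pct = 100.0 * (prof[ch] - away[ch]) / away[ch]
                rows.append({"domain": domain.value, "condition": att.value,
                             "channel": ch, "power_change_pct": pct})
        return pd.DataFrame(rows)

    def _frequency_stats(self, csd_trials, by_cond,
                         hotspots) -> StatsResult | None:
        """Kruskal-Wallis battery over per-trial cycle frequencies."""
        groups = {}
        for domain in Domain:
            ch = hotspots.channel(domain)
            if ch is None:
                continue
            freqs = []
            for i in by_cond[Attention.ATTEND_IN]:
                trial = csd_trials[i]
                nb = gammafreq.bandpass_gamma(trial.data[ch], trial.fs)
                phase, amp = gammafreq.analytic_phase_amplitude(nb, trial.fs)
                sl = window_slice(trial.epochs, trial.fs, "mc23")
                cs = gammafreq.detect_gamma_troughs(phase, amp, sl, trial.fs)
                if cs.accepted_periods_s.size:
                    freqs.append(1.0 / np.median(cs.accepted_periods_s))
            if len(freqs) >= 2:
                groups[domain.value] = np.asarray(freqs)
        if len(groups) < 2:
            return None
        return compare_independent_groups(groups)

    def _esa_gamma_power(self, esa_trials: list[EsaTrial], bank: WaveletBank,
                         band) -> np.ndarray:
        sub = bank.restrict(band)
        acc = None
        for trial in esa_trials:
            sl = window_slice(trial.epochs, trial.fs, "mc23")
            tfr = wavelet_transform(trial.data, sub)
            psd = psd_spectrum(tfr, window=sl, one_over_f_correct=True)
            prof = psd.mean(axis=0)
            acc = prof if acc is None else acc + prof
        return acc / len(esa_trials)

    def _windowed_phasors(self, trial, channels, sub: WaveletBank):
        """Unit phasors (channels x freqs x window samples) of one trial."""
        sl = window_slice(trial.epochs, trial.fs, "mc23")
        tfr = wavelet_transform(trial.data[channels], sub)
        vals = tfr.values[:, :, sl]  # freqs x channels x time
        mag = np.abs(vals)
        mag[mag == 0] = 1.0
        return np.transpose(vals / mag, (1, 0, 2)).astype(np.complex64)

    def _phc_esa_profiles(self, csd_in, esa_in, hotspots, bank,
                          esa_channels) -> dict[Domain, PhcProfile]:
        """Streamed CSD-ESA PhC: accumulate trial phasor products."""
        cfg = self.config
        sub = bank.restrict(cfg.esa_band)
        refs = [(d, hotspots[d].channel) for d in Domain
                if hotspots[d].channel is not None
                and hotspots[d].passes_inclusion is not False]
        if not refs or len(csd_in) < 2:
            return {}
        acc = None
        n = 0
        for csd_trial, esa_trial in zip(csd_in, esa_in):
            ref_ph = self._windowed_phasors(csd_trial,
                                            [ch for _, ch in refs], sub)
            tgt_ph = self._windowed_phasors(esa_trial, esa_channels, sub)
            prod = ref_ph[:, None] * np.conj(tgt_ph[None, :])
            acc = prod if acc is None else acc + prod
            n += 1
        plv = np.abs(acc / n).mean(axis=-1)  # refs x targets x freqs
        ev = coherence.expected_plv(n)
        out = {}
        n_channels = self.session.probe.n_channels
        for r, (domain, ref_ch) in enumerate(refs):
            values = np.full((n_channels, sub.f0_hz.size), np.nan)
            for t, ch in enumerate(esa_channels):
                values[ch] = plv[r, t] - ev
            out[domain] = PhcProfile(values=values, f0_hz=sub.f0_hz,
                                     n_trials=n, kind=PairKind.CSD_ESA,
                                     reference_channel=ref_ch)
        return out

    def _preference(self, phc_profiles, esa_band, probe):
        if set(phc_profiles) != set(Domain):
            return None
        means = {d: np.clip(phc_profiles[d].gamma_band_mean(esa_band),
                            0.0, None)
                 for d in Domain}
        return coherence.normalized_domain_preference(
            means[Domain.SG], means[Domain.G], means[Domain.IG])

    def _phc_contrasts(self, csd_in, csd_nearby, hotspots, assignment,
                       bank, band) -> pd.DataFrame:
        sub = bank.restrict(band)
        rows = []
        channels = list(range(self.session.probe.n_channels))
        pairs = [(dr, do) for dr, do in CONTRAST_PAIRS
                 if hotspots[dr].channel is not None
                 and hotspots[do].channel is not None]
        if not pairs:
            return pd.DataFrame(rows)
        gamma_means = {}
        for cond_name, trials in (("attend_in", csd_in),
                                  ("attend_nearby", csd_nearby)):
            acc, n = None, 0
            for trial in trials:
                ph = self._windowed_phasors(trial, channels, sub)
                refs = ph[[hotspots[dr].channel for dr, _ in pairs]]
                prod = refs[:, None] * np.conj(ph[None, :])
                acc = prod if acc is None else acc + prod
                n += 1
            plv = np.abs(acc / n).mean(axis=-1) - coherence.expected_plv(n)
            gamma_means[cond_name] = plv.mean(axis=-1)  # pairs x channels
        for p, (dom_ref, dom_other) in enumerate(pairs):
            ref_ch = hotspots[dom_ref].channel
            partners = [c for c in assignment.channels_of(dom_other)
                        if abs(c - ref_ch) > 1]
            try:
                phc_in, phc_nearby, partner = coherence.attention_phc_contrast(
                    gamma_means["attend_in"][p],
                    gamma_means["attend_nearby"][p], partners)
            except ValueError:
                continue
            rows.append({"pair": f"{dom_ref.value}/{dom_other.value}",
                         "hotspot_channel": ref_ch,
                         "partner_channel": partner,
                         "phc_attend_in": phc_in,
                         "phc_attend_nearby": phc_nearby,
                         "delta": phc_in - phc_nearby})
        return pd.DataFrame(rows)


@dataclass
class LaminarGammaResults:
    """Everything :meth:`LaminarGammaModel.fit` computed for one session."""

    model: LaminarGammaModel
    gamma_band: tuple[float, float]
    evoked_csd: CsdTrial
    border_initial_um: float
    assignment: LaminarAssignment
    baseline_correlation: np.ndarray
    power_profiles: dict[Attention, np.ndarray]
    baseline_power_profile: np.ndarray | None
    hotspots: HotspotSet
    dominant_frequency: pd.DataFrame
    attention_power_modulation: pd.DataFrame | None
    frequency_stats: StatsResult | None
    esa_channels: list[int] | None
    esa_gamma_power: np.ndarray | None
    phc_esa_profiles: dict[Domain, PhcProfile]
    phc_preference: np.ndarray | None
    phc_contrasts: pd.DataFrame | None
    attention_analyses_skipped: bool = False

    @property
    def border_um(self) -> float:
        return self.assignment.border_l3l4_um

    def dominant_freq_hz(self, domain: Domain | str,
                         condition: Attention | str) -> float:
        df = self.dominant_frequency
        sel = df[(df.domain == Domain(domain).value)
                 & (df.condition == Attention(condition).value)]
        if sel.empty:
            raise KeyError((domain, condition))
        return float(sel.freq_hz.iloc[0])

    def power_change_pct(self, domain: Domain | str,
                         condition: Attention | str = Attention.ATTEND_IN,
                         ) -> float:
        if self.attention_power_modulation is None:
            raise ValueError("attention analyses were skipped")
        df = self.attention_power_modulation
        sel = df[(df.domain == Domain(domain).value)
                 & (df.condition == Attention(condition).value)]
        if sel.empty:
            raise KeyError((domain, condition))
        return float(sel.power_change_pct.iloc[0])

    def domain_preference_means(self) -> pd.DataFrame | None:
        """Mean normalized PhC preference of each hotspot within each domain."""
        if self.phc_preference is None:
            return None
        rows = []
        for r, ref in enumerate(Domain):
            for tgt in Domain:
                chans = [c for c in self.assignment.channels_of(tgt)
                         if np.isfinite(self.phc_preference[r, c])]
                if not chans:
                    continue
                rows.append({"reference": ref.value, "esa_domain": tgt.value,
                             "mean_preference":
                                 float(np.mean(self.phc_preference[r, chans]))})
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = []
        a = lines.append
        probe = self.model.session.probe
        a("Laminar gamma-oscillation analysis")
        a("=" * 50)
        a(f"Trials: {len(self.model.session)}   "
          f"channels: {probe.n_channels} @ {probe.pitch_um:.0f} um   "
          f"performance: {self.model.session.performance:.2f}")
        a(f"Gamma band: {self.gamma_band[0]:.1f}-{self.gamma_band[1]:.1f} Hz")
        a(f"Layer III/IV border: {self.border_um:.0f} um "
          f"(initial {self.border_initial_um:.0f} um)")
        counts = {d.value: len(self.assignment.channels_of(d))
                  for d in Domain}
        a(f"Domains (channels): {counts}")
        a("")
        a("Hotspots:")
        for domain in Domain:
            h = self.hotspots[domain]
            if h.channel is None:
                a(f"  {domain.value:3s}: none")
            else:
                depth = probe.depth_of(h.channel)
                a(f"  {domain.value:3s}: channel {h.channel} "
                  f"({depth:.0f} um, {h.method.value}, "
                  f"inclusion={'?' if h.passes_inclusion is None else h.passes_inclusion})")
        if not self.dominant_frequency.empty:
            a("")
            a("Dominant gamma frequency (Hz):")
            piv = self.dominant_frequency.pivot(index="domain",
                                                columns="condition",
                                                values="freq_hz")
            a(piv.round(2).to_string())
        if (self.attention_power_modulation is not None
                and not self.attention_power_modulation.empty):
            a("")
            a("Gamma-power change vs attend-away (%):")
            piv = self.attention_power_modulation.pivot(
                index="domain", columns="condition",
                values="power_change_pct")
            a(piv.round(1).to_string())
        pref = self.domain_preference_means()
        if pref is not None and not pref.empty:
            a("")
            a("Mean normalized ESA PhC preference (reference x ESA domain):")
            piv = pref.pivot(index="reference", columns="esa_domain",
                             values="mean_preference")
            a(piv.round(3).to_string())
        if self.phc_contrasts is not None and not self.phc_contrasts.empty:
            a("")
            a("Attention PhC contrast (hotspot/partner):")
            a(self.phc_contrasts.round(4).to_string(index=False))
        if self.attention_analyses_skipped:
            a("")
            a("NOTE: behavioral performance below threshold; attention "
              "analyses skipped.")
        return "\n".join(lines)

    def save_report(self, out_dir: str | Path) -> Path:
        """Write CSV tables and a JSON stats bundle; deterministic."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        probe = self.model.session.probe
        prof = pd.DataFrame({"channel": np.arange(probe.n_channels),
                             "depth_um": probe.depths_um,
                             "domain": [d.value for d in
                                        self.assignment.domains]})
        for att, p in self.power_profiles.items():
            prof[f"gamma_power_{att.value}"] = p
        if self.baseline_power_profile is not None:
            prof["gamma_power_baseline"] = self.baseline_power_profile
        prof.to_csv(out / "gamma_power_profile.csv", index=False)

        rows = []
        for domain in Domain:
            h = self.hotspots[domain]
            rows.append({"domain": domain.value, "channel": h.channel,
                         "method": h.method.value,
                         "gamma_power": h.gamma_power,
                         "passes_inclusion": h.passes_inclusion})
        pd.DataFrame(rows).to_csv(out / "hotspots.csv", index=False)
        self.dominant_frequency.to_csv(out / "dominant_frequency.csv",
                                       index=False)
        if self.attention_power_modulation is not None:
            self.attention_power_modulation.to_csv(
                out / "attention_power_modulation.csv", index=False)
        if self.phc_contrasts is not None:
            self.phc_contrasts.to_csv(out / "phc_contrasts.csv", index=False)
        pref = self.domain_preference_means()
        if pref is not None:
            pref.to_csv(out / "phc_preference.csv", index=False)
        for domain, profile in self.phc_esa_profiles.items():
            df = pd.DataFrame(profile.values,
                              columns=[f"{f:.2f}Hz" for f in profile.f0_hz])
            df.insert(0, "channel", np.arange(probe.n_channels))
            df.to_csv(out / f"phc_esa_{domain.value}.csv", index=False)

        stats_bundle = {
            "gamma_band_hz": list(self.gamma_band),
            "border_um": self.border_um,
            "attention_analyses_skipped": self.attention_analyses_skipped,
        }
        if self.frequency_stats is not None:
            fs = self.frequency_stats
            stats_bundle["hotspot_frequency_comparison"] = {
                "test": fs.test, "statistic": fs.statistic, "df": fs.df,
                "p": fs.p, "n_per_group": fs.n_per_group,
                "posthoc": (fs.posthoc.to_dict(orient="records")
                            if fs.posthoc is not None else None),
            }
        (out / "stats.json").write_text(json.dumps(stats_bundle, indent=1,
                                                   default=float),
                                        encoding="utf-8")
        (out / "summary.txt").write_text(self.summary() + "\n",
                                         encoding="utf-8")
        return out


def run_full_pipeline(session_dir: str | Path,
                      config: PipelineConfig | None = None,
                      out_dir: str | Path | None = None,
                      verbose: bool = False) -> LaminarGammaResults:
    """Read a session directory, fit the model, optionally write a report."""
    model = LaminarGammaModel.from_directory(session_dir, config=config)
    results = model.fit(verbose=verbose)
    if out_dir is not None:
        results.save_report(out_dir)
    return results
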