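# guildspec

Microbial communities are typically organized into **guilds** — groups
of taxa with similar resource preferences that therefore compete for the
same resources. Direct measurement of who eats what inside a complex
community is rarely possible, but abundance **time series** are cheap
and abundant. `guildspec` is a toolkit for inferring the structure of
resource competition from such series, built around a simple
observation: because resource supply fluctuates in time, the temporal
coupling between two species carries information about their shared
resource use — but only if you look across timescales.

It is aimed at quantitative ecologists and systems biologists who want
to (a) benchmark pairwise association metrics on communities with known
ground truth, and (b) apply the same metrics to real relative-abundance
tables.

## The model and the metrics

The generator is an environment-mediated consumer-resource model: N
species x_i and M resources R_α with

    dx_i/dt = x_i ( Σ_α r_iα γ_iα R_α − d_x )
    dR_α/dt = K_α(t) − ( d_R + Σ_i r_iα x_i ) R_α

driven by a time-dependent supply K_α(t), either sinusoidal or an
Ornstein–Uhlenbeck process. Species–resource adjacency has a planted
block (guild) structure tuned by a bias q (p_in = 0.5 + q inside a
guild's preferred resource block, p_out = 0.5 − q outside), plus one
private resource per species. The ground truth for inference is the
resource-utilization overlap **GG⊤**, with G_iα = r_iα γ_iα.

From log-z-scored abundance series s_i(t) the package computes four
pairwise measures: the equal-time correlation C_ij(0), its absolute
value, and two spectral aggregates built from Welch-averaged cross
spectra P_ij(f) — the total CPSD magnitude 𝒫_ij = Σ_k |P_ij(f_k)| Δf
and the total coherence 𝒯𝒞_ij = Σ_k |P_ij|²/(P_ii P_jj) Δf, integrated
up to the Nyquist frequency with Δf = f_max/15. Thresholding a metric
matrix and taking single-linkage clusters yields inferred links and
guilds, scored against GG⊤ by Spearman correlation and ROC/AUC. An
empirical mode applies the same metrics to taxa × day tables and tests
their association with Jukes–Cantor sequence distance against an
index-shuffle null.

Why the spectral metrics matter: C(0) flips sign with the drive
timescale (fast supply fluctuations synchronize guild members, slow
ones put them in competition-driven antiphase), so without knowing the
environment's timescale the plain correlation can be actively
misleading. The CPSD magnitude and coherence aggregate coupling over
all lags and are insensitive to those phase relations.

## Worked example

```python
import guildspec as gs

spec = gs.EnsembleSpec(n_species=6, n_resources=30, n_guilds=2,
                       guild_bias=0.4, drive_kind="ou", omega=1.0,
                       t_final=20000.0, sampling_interval=1.0)
real = gs.run_realization(spec, network_seed=1, drive_seed=2)
print("guild labels:", real.network.guild_labels)
for name in gs.METRIC_NAMES:
    rho, p = gs.spearman_vs_overlap(real.metrics[name], real.network.overlap)
    auc = gs.guild_roc(real.metrics[name], real.network.guild_labels).auc
    print(f"{name:>15s}  spearman={rho:+.2f} (p={p:.1e})  guild AUC={auc:.2f}")
```

Output:

```
guild labels: [0 0 0 1 1 1]
             C0  spearman=-0.37 (p=1.7e-01)  guild AUC=0.41
          absC0  spearman=+0.40 (p=1.4e-01)  guild AUC=0.72
     total_cpsd  spearman=+0.70 (p=4.0e-03)  guild AUC=1.00
total_coherence  spearman=+0.97 (p=9.0e-10)  guild AUC=1.00
```

Two guilds of three species each; under an OU-driven environment the
equal-time correlation is uninformative (AUC 0.41, i.e., chance), the
absolute correlation helps a little, and both spectral metrics recover
the guild partition perfectly, with total coherence ranking pair
overlaps almost exactly (ρ = 0.97).

A command-line interface wraps the same machinery
(`guildspec simulate|metrics|evaluate|sweep|field`, each with
`--config`/`--seed`/`--outdir`); see `guildspec --help`.

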