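# vollearn

Adaptive learning under outcome volatility: simulation and analysis of a
three-block probabilistic learning task in which the volatility of win and
loss outcomes is manipulated independently, together with the
reinforcement-learning modelling, behavioural statistics and pupillometry
inference used to compare participant groups on it.

The package is aimed at computational-psychiatry researchers who want a
tested, fully synthetic-data-driven implementation of this analysis chain:
every stage — task generation, agents, fitting, ANOVAs, cluster
permutation tests — runs end-to-end on a built-in three-group cohort
(RA: recovered from anorexia nervosa, n = 25; EA: elevated eating-disorder
symptoms, n = 25; HC: healthy controls, n = 32), so the pipeline is
exercisable and checkable without any participant data.

## The task and the model

Each of 3 blocks has 80 trials with two shapes, A and B. On every trial
one shape carries the win and one the loss, independently of each other;
the probability that shape A carries an outcome is either **volatile**
(alternating between 0.85 and 0.15 every 14–30 trials, averaging 0.5 per
block) or **stable** (fixed at 0.5). Block 1 is volatile for both
valences; blocks 2 and 3 each hold one valence stable, in counterbalanced
order. Both shapes' outcomes are shown regardless of choice. A win adds
15p to a total initialised at £1.50; a loss removes 15p.

Behaviour is modelled with a valenced Rescorla–Wagner learner. With
r<sub>t</sub>, l<sub>t</sub> ∈ {0, 1} indicating whether shape A carried
the win / loss on trial t:

    v_win(t+1)  = v_win(t)  + α_win  (r_t − v_win(t))
    v_loss(t+1) = v_loss(t) + α_loss (l_t − v_loss(t))
    P(choose A) = σ( 2β [v_win(t) − v_loss(t)] + b )

The winning model gives each block × valence cell its own learning rate
α (6 in total), one inverse temperature β across the task, and no bias b.
The primary outcome is the **learning-rate adjustment**: a subject's α
under volatile outcomes (block 1 pooled with the valence-volatile block)
minus α in the valence-stable block, per valence.

Around this core the package provides MAP fitting and adaptive
random-walk Metropolis sampling on transformed scales, integrated-BIC
model comparison over an empirical-Bayes group prior, parameter-recovery
and posterior-predictive harnesses, switch/stay statistics, full-factorial
mixed ANOVAs with Greenhouse–Geisser correction, Welch and one-sample
t-tests, Fisher r-to-z comparison of correlations, and a pupillometry
pipeline (blink interpolation, outcome-locked epoching, condition
contrasts, cluster-mass permutation tests with group labels shuffled
between subjects and valence labels flipped within subjects).

## Worked example

`examples/03_behaviour_statistics.py` simulates a reduced cohort
(8 subjects per group), fits the winning model and runs the main
behavioural statistics. It prints (abridged):

```
fitted mean adjustment by group (volatile minus stable learning rate):
        mean    std
EA     0.143  0.127
HC     0.063  0.195
RA     0.207  0.137

one-sample t of the valence-stacked adjustments against 0:
  EA: t(15) = 3.05, p = 0.0081
  HC: t(15) = 1.11, p = 0.2843
  RA: t(15) = 3.98, p = 0.0012

Fisher r-to-z, r=.512 (n 24) vs r=-.176 (n 30): z = 2.55, p = 0.011
```

The group means are the fitted learning-rate adjustments — positive
values mean learning speeds up under volatility — and the t-tests ask
whether each group adjusts at all. The other examples cover schedule
generation, single-agent recovery, iBIC model comparison, the pupil
cluster analysis, and the full pipeline (also available as the
`vollearn run-all` command).

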