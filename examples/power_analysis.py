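"""Sample-size planning for a within-participants comparison.

Uses the exact noncentral-t power function: for a paired t-test with
standardized effect d_z, power at sample size n is
P(T > t_crit | df = n−1, ncp = d_z·√n) (+ the mirror tail if two-sided).
"""

from operant import required_n_paired

n = required_n_paired(d_z=0.4, power=0.80, alpha=0.05, tails=2)
print(f"d_z = 0.4, 80% power, two-tailed alpha = .05  ->  n = {n}")
# d_z = 0.4 is a common 'smallest effect of interest' in psychology; the
# solver shows that a properly powered within-participants study needs
# more than 50 participants.

for d in (0.2, 0.3, 0.5, 0.8):
    print(f"d_z = {d}: n = {required_n_paired(d)}")
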