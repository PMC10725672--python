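"""How many DNA sequences comply perfectly with intrastrand symmetry?

For even length N the exact count of sequences with #A = #T and #G = #C is
(C(N, N/2))^2, about 4^N * 2/(pi*N); for odd N it is zero.  The normalized
ratio count*N/4^N rises monotonically to 2/pi ~ 0.6366, while the raw
fraction count/4^N vanishes: perfectly symmetric sequences form a thin
lattice in sequence space.
"""
import math

from csprkit import (asymptotic_ratio, count_symmetric_closed,
                     count_symmetric_enumerate)

print(" N   exact count          count*N/4^N   count/4^N")
for n in (2, 4, 6, 8, 10, 100, 10_000):
    r = count_symmetric_closed(n)
    count = (f"10^{r.log_count / math.log(10):.1f}" if n > 10
             else str(r.exact_count))
    print(f"{n:5d}  {count:>18s}  {r.ratio:.6f}    {r.ratio / n:.3e}")
print(f"\nlimit of count*N/4^N = 2/pi = {2 / math.pi:.6f}")
print("cross-check against brute-force enumeration at N <= 10:",
      all(count_symmetric_closed(n).exact_count
          == count_symmetric_enumerate(n) for n in range(0, 11)))
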