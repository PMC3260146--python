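VV  synthetic progesterone-response-element matrices (stand-ins authored for this package; not database-derived)
XX
//
ID  V$PR_01
XX
BF  Progesterone receptor (full PRE, high-affinity variant; synthetic)
XX
P0      A      C      G      T
01      5      5     85      5      G
02     25     25     25     25      N
03     85      5      5      5      A
04      5     85      5      5      C
05     85      5      5      5      A
06     25     25     25     25      N
07     25     25     25     25      N
08     25     25     25     25      N
09      5      5      5     85      T
10      5      5     85      5      G
11      5      5      5     85      T
12     25     25     25     25      N
13      5     85      5      5      C
XX
//
ID  V$PR_02
XX
BF  Progesterone receptor (full PRE; synthetic)
XX
P0      A      C      G      T
01      8      8     76      8      G
02     40     20     20     20      A
03     76      8      8      8      A
04      8     76      8      8      C
05     76      8      8      8      A
06     30     30     20     20      N
07     20     30     30     20      N
08     20     20     30     30      N
09      8      8      8     76      T
10      8      8     76      8      G
11      8      8      8     76      T
12     20     20     20     40      T
13      8     76      8      8      C
XX
//
ID  V$PR_Q2
XX
BF  Progesterone receptor (half-site PRE; synthetic)
XX
P0      A      C      G      T
01      7      7      7     79      T
02      7      7     79      7      G
03      7      7      7     79      T
04     10     30     10     50      T
05      7     79      7      7      C
06     10     20     10     60      T
XX
//
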