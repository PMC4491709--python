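# The 54 connected ordered 3-node substructures

Pair slots are (bottom,middle), (bottom,top), (middle,top) with rank
ascending bottom < middle < top. UP = link from the lower- to the
higher-rank node, DOWN the reverse, BIDIR both. `(q,s)` is the
package's deterministic numbering: classes sorted by link count then
canonical edge set, members in lexicographic code order. Named
substructures: fan_in_up = (3, 1), up_chain = (2, 5), fan_out_up = (1, 3).

| q | s | code | links | up | down |
|---|---|------|-------|----|------|
| 1 | 1 | NONE|DOWN|DOWN | 2 | 0 | 2 |
| 1 | 2 | DOWN|NONE|UP | 2 | 1 | 1 |
| 1 | 3 | UP|UP|NONE | 2 | 2 | 0 |
| 2 | 1 | NONE|DOWN|UP | 2 | 1 | 1 |
| 2 | 2 | NONE|UP|DOWN | 2 | 1 | 1 |
| 2 | 3 | DOWN|NONE|DOWN | 2 | 0 | 2 |
| 2 | 4 | DOWN|UP|NONE | 2 | 1 | 1 |
| 2 | 5 | UP|NONE|UP | 2 | 2 | 0 |
| 2 | 6 | UP|DOWN|NONE | 2 | 1 | 1 |
| 3 | 1 | NONE|UP|UP | 2 | 2 | 0 |
| 3 | 2 | DOWN|DOWN|NONE | 2 | 0 | 2 |
| 3 | 3 | UP|NONE|DOWN | 2 | 1 | 1 |
| 4 | 1 | NONE|DOWN|BIDIR | 3 | 1 | 2 |
| 4 | 2 | NONE|BIDIR|DOWN | 3 | 1 | 2 |
| 4 | 3 | DOWN|NONE|BIDIR | 3 | 1 | 2 |
| 4 | 4 | UP|BIDIR|NONE | 3 | 2 | 1 |
| 4 | 5 | BIDIR|NONE|UP | 3 | 2 | 1 |
| 4 | 6 | BIDIR|UP|NONE | 3 | 2 | 1 |
| 5 | 1 | DOWN|DOWN|DOWN | 3 | 0 | 3 |
| 5 | 2 | DOWN|DOWN|UP | 3 | 1 | 2 |
| 5 | 3 | DOWN|UP|UP | 3 | 2 | 1 |
| 5 | 4 | UP|DOWN|DOWN | 3 | 1 | 2 |
| 5 | 5 | UP|UP|DOWN | 3 | 2 | 1 |
| 5 | 6 | UP|UP|UP | 3 | 3 | 0 |
| 6 | 1 | NONE|UP|BIDIR | 3 | 2 | 1 |
| 6 | 2 | NONE|BIDIR|UP | 3 | 2 | 1 |
| 6 | 3 | DOWN|BIDIR|NONE | 3 | 1 | 2 |
| 6 | 4 | UP|NONE|BIDIR | 3 | 2 | 1 |
| 6 | 5 | BIDIR|NONE|DOWN | 3 | 1 | 2 |
| 6 | 6 | BIDIR|DOWN|NONE | 3 | 1 | 2 |
| 7 | 1 | DOWN|UP|DOWN | 3 | 1 | 2 |
| 7 | 2 | UP|DOWN|UP | 3 | 2 | 1 |
| 8 | 1 | DOWN|DOWN|BIDIR | 4 | 1 | 3 |
| 8 | 2 | UP|BIDIR|DOWN | 4 | 2 | 2 |
| 8 | 3 | BIDIR|UP|UP | 4 | 3 | 1 |
| 9 | 1 | NONE|BIDIR|BIDIR | 4 | 2 | 2 |
| 9 | 2 | BIDIR|NONE|BIDIR | 4 | 2 | 2 |
| 9 | 3 | BIDIR|BIDIR|NONE | 4 | 2 | 2 |
| 10 | 1 | DOWN|UP|BIDIR | 4 | 2 | 2 |
| 10 | 2 | DOWN|BIDIR|DOWN | 4 | 1 | 3 |
| 10 | 3 | UP|DOWN|BIDIR | 4 | 2 | 2 |
| 10 | 4 | UP|BIDIR|UP | 4 | 3 | 1 |
| 10 | 5 | BIDIR|DOWN|UP | 4 | 2 | 2 |
| 10 | 6 | BIDIR|UP|DOWN | 4 | 2 | 2 |
| 11 | 1 | DOWN|BIDIR|UP | 4 | 2 | 2 |
| 11 | 2 | UP|UP|BIDIR | 4 | 3 | 1 |
| 11 | 3 | BIDIR|DOWN|DOWN | 4 | 1 | 3 |
| 12 | 1 | DOWN|BIDIR|BIDIR | 5 | 2 | 3 |
| 12 | 2 | UP|BIDIR|BIDIR | 5 | 3 | 2 |
| 12 | 3 | BIDIR|DOWN|BIDIR | 5 | 2 | 3 |
| 12 | 4 | BIDIR|UP|BIDIR | 5 | 3 | 2 |
| 12 | 5 | BIDIR|BIDIR|DOWN | 5 | 2 | 3 |
| 12 | 6 | BIDIR|BIDIR|UP | 5 | 3 | 2 |
| 13 | 1 | BIDIR|BIDIR|BIDIR | 6 | 3 | 3 |
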