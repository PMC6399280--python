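key	row	col
º	0	0
1	0	1
2	0	2
3	0	3
4	0	4
5	0	5
6	0	6
7	0	7
8	0	8
9	0	9
0	0	10
'	0	11
¡	0	12
q	1	1
w	1	2
e	1	3
r	1	4
t	1	5
y	1	6
u	1	7
i	1	8
o	1	9
p	1	10
`	1	11
+	1	12
a	2	1
s	2	2
d	2	3
f	2	4
g	2	5
h	2	6
j	2	7
k	2	8
l	2	9
ñ	2	10
´	2	11
<	3	0
z	3	1
x	3	2
c	3	3
v	3	4
b	3	5
n	3	6
m	3	7
,	3	8
.	3	9
-	3	10
 	4	5.5
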