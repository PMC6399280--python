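key	row	col
`	0	0
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
-	0	11
=	0	12
q	1	0
w	1	1
e	1	2
r	1	3
t	1	4
y	1	5
u	1	6
i	1	7
o	1	8
p	1	9
[	1	10
]	1	11
a	2	0
s	2	1
d	2	2
f	2	3
g	2	4
h	2	5
j	2	6
k	2	7
l	2	8
;	2	9
'	2	10
#	2	11
z	3	0
x	3	1
c	3	2
v	3	3
b	3	4
n	3	5
m	3	6
,	3	7
.	3	8
/	3	9
 	4	4.5
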