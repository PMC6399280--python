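secondary	primary
á	a
é	e
í	i
ó	o
ú	u
ü	u
à	a
è	e
ì	i
ò	o
ù	u
ç	c
!	1
"	2
·	3
$	4
%	5
&	6
/	7
(	8
)	9
=	0
?	'
¿	¡
^	`
*	+
¨	´
;	,
:	.
_	-
>	<
ª	º
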