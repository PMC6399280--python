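el tren de la mañana llegó tarde otra vez y el andén se llenó poco a poco de gente leyendo las noticias en el teléfono
ella sirvió el té y miró la lluvia caer por la ventana de la cocina mientras el agua se enfriaba en el fuego
mucha gente piensa que aprender un idioma nuevo es cosa de jóvenes pero los adultos también pueden avanzar con constancia
el informe muestra que el número de visitantes de los parques nacionales lleva tres años creciendo sin pausa
él guardó las últimas cajas y las bajó por la escalera estrecha hasta la furgoneta que esperaba en la calle
no hay nada como el olor del pan recién hecho saliendo del horno en una fría mañana de invierno
la maestra pidió a los niños que escribieran un cuento corto sobre algo amable que hubieran hecho en las vacaciones
después de cenar pasearon por la playa y vieron volver las barcas de pesca al puerto con la marea
el comité se reunirá el jueves para hablar del presupuesto del próximo año y de los planes para la nueva sala
es importante beber mucha agua cuando se trabaja al aire libre en el calor de los meses de verano
los ingenieros revisaron cada tornillo del puente antes de abrir la carretera al tráfico por la tarde
su abuela cuidaba un pequeño huerto detrás de la casa donde crecían judías zanahorias y tomates rojos y dulces
la película empieza a las ocho así que debemos salir de casa a las siete y media para encontrar buen sitio
muchas aves recorren miles de kilómetros cada otoño para pasar el invierno en países más cálidos del sur
estuvo pensando en la carta todo el día y al final decidió contestarla con honradez y de inmediato
la biblioteca abre todos los días menos el domingo y la sala de lectura del piso de arriba está tranquila a primera hora
los científicos han descubierto que dormir bien mejora la memoria y la atención de las personas de todas las edades
el mercado de la plaza vende queso flores y libros de segunda mano todos los sábados por la mañana hasta el mediodía
ella giró la llave despacio y empujó la pesada puerta que daba al pasillo oscuro y silencioso de la vieja casa
la receta lleva dos huevos una taza de harina y un poco de mantequilla derretida a fuego lento
cuando por fin llegó el autobús venía tan lleno que decidimos hacer a pie el resto del camino hasta el centro
la empresa anunció que construiría una fábrica nueva cerca del puerto creando varios cientos de puestos de trabajo
los niños cantaban en la habitación de al lado y el sonido llegaba suave por toda la casa
nadie había tocado la caja en años y una fina capa de polvo cubría las fotografías de dentro
el médico escuchó con atención y luego explicó el tratamiento con palabras sencillas y fáciles de entender
conviene llevar algo de abrigo porque las tardes en la montaña pueden ser sorprendentemente frías
el cuarteto tocó casi dos horas y el público se puso en pie para aplaudir al final de la noche
escribió la dirección en el dorso de un sobre y prometió enviar el paquete a la mañana siguiente
el sendero del bosque estaba marcado con pequeñas señales de madera clavadas en los troncos más altos
pensándolo otra vez comprendió que la primera respuesta había sido la buena desde el principio
el equipo trabajó todo el fin de semana para terminar el proyecto antes del plazo del lunes
por la tarde se levantó un viento fuerte y los marineros prefirieron quedarse en el puerto hasta que pasara
el museo tiene una exposición nueva sobre la historia de la imprenta y la hechura de los primeros libros
todo en la carta tenía buen aspecto pero al final los dos pidieron la sopa y el pollo asado
la enfermera le tomó la temperatura y anotó el dato en la hoja que colgaba a los pies de la cama
había una cola larga delante del teatro y las entradas se agotaron en la primera hora
los estudiantes pasaron la mañana en el laboratorio midiendo el crecimiento de las plantas bajo luces distintas
llovió durante la noche y las calles aún brillaban cuando las primeras tiendas abrieron sus puertas
su hermano trabaja en el ferrocarril y conoce el horario de todos los trenes que pasan por la estación
el viejo reloj del vestíbulo da las horas con una nota grave y firme que se oye desde arriba
ella guarda las cartas en una caja de madera en el estante que hay sobre el escritorio del estudio
la luz clara de la mañana llenó la habitación y calentó la mesa donde ya esperaba el desayuno
plantaron un manzano en medio del jardín el día en que nació su hija
el ministro contestó la pregunta con brevedad y pasó después al asunto de las escuelas nuevas
el panadero empieza a trabajar mucho antes del amanecer para que el primer pan esté listo cuando despierta el pueblo
algo en la calle tranquila le hizo detenerse y mirar la casa una vez más
la reunión terminó pronto y todos estuvieron de acuerdo en que el plan nuevo era mejor que el antiguo
el río nace en las colinas del norte y llega al mar tras un viaje de ciento treinta kilómetros
en la cresta alta apenas crece nada salvo hierba dura y unos pocos pinos retorcidos
la tienda de la esquina vende sellos y periódicos y está abierta hasta bien entrada la tarde
leer con poca luz cansa la vista pero no la daña de manera duradera
la cantante dio las gracias al público y prometió volver a la ciudad la primavera siguiente
su casa está al final del camino detrás de un seto alto y una cancela blanca de madera
lo primero que hace ella cada mañana es abrir la ventana y escuchar a los pájaros del jardín
la impresora se ha quedado otra vez sin papel así que el informe tendrá que esperar a la tarde
aprendió a nadar en el agua fría del lago el verano en que cumplió siete años
sonó dos veces la campana y los niños recogieron sus libros y salieron deprisa al patio
nadie recordaba cuándo empezó la tradición pero todo el pueblo la guardaba con fidelidad
la carretera sube con fuerza durante cinco kilómetros y baja luego suavemente al valle verde
ella afiló el lápiz cogió una hoja limpia y empezó a dibujar el frutero de la mesa
a la sopa le falta un poco de sal y quizá una cucharada de nata justo antes de servirla
la última luz del día tocó lo alto de las torres y volvió de oro las ventanas
cada cosa del taller tenía su sitio y las herramientas colgaban en filas ordenadas a lo largo de la pared
el tren de la costa sale del andén del fondo a las diez y diez
su respuesta fue corta y sincera y el entrevistador le dio las gracias y pasó a la siguiente pregunta
el jardín estaba lleno del rumor de las abejas trabajando entre las flores de la tarde templada
piensa bien antes de firmar los papeles y pregunta por todo aquello que no quede claro
el barco zarpó al amanecer con viento suave del oeste y mar en calma por delante
se sentaron en el banco junto al estanque y compartieron los bocadillos que habían traído de casa
el joven médico se mudó al pueblo en primavera y se quedó allí cuarenta años
la idea del largo viaje de vuelta hizo que la tarde pareciera más corta de lo que era
un buen mapa y unas botas fuertes es todo lo que hace falta para disfrutar del monte en otoño
el empleado selló el impreso sonrió con amabilidad y señaló el camino hacia el segundo piso
las cartas estaban atadas con un cordel y ordenadas por fechas en el cajón de abajo del escritorio
nada se decidió en la primera reunión pero todos se fueron con mucho en que pensar
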